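# ntba

Biophysical scanning of **nonspecific transcription-factor binding affinity
(nTBA)** along DNA, and an integration pipeline that combines nTBA with
epigenomic tracks and Hi-C intra-chromosomal contacts to classify fixed-size
genomic bins into **Inactive / Poised / Active Genomic Zones**.

## Who this is for

Regulatory-genomics researchers who want a sequence-intrinsic binding signal
that does not depend on calling specific motif matches: promoters, enhancers
and in particular HOT (high-occupancy target) regions attract many TFs
without harbouring matching canonical motifs, and an ensemble-averaged
*nonspecific* affinity is one quantitative handle on that behaviour. The
package also provides the downstream integration: given Hi-C contacts and
marker tracks, it segments a chromosome into three interaction/activity
regimes.

## The model

For a sliding window *Sᵢ* (L = 50 bp, step 5 bp) and a TF with binding-energy
matrix *E* (derived from its PWM; consensus base = energy 0), the window
affinity is

```
Aᵢ = p · Σ_{l=1}^{L−m+1} P(E·Sᵢ,ₗ)
```

where the binding probability *P* is either the **Fermi–Dirac** form
`P = 1/(1 + exp(E·S − μ))` with chemical potential μ (TF concentration), or
its low-concentration **Maxwell–Boltzmann** limit `P = exp(−E·S)`. Both
strands are scored. Local composition bias is removed by subtracting the mean
affinity over R mononucleotide shuffles of the window:

```
dbAᵢ = Aᵢ − Aᵢ,R        (differential binding affinity)
nTBA(Sᵢ) = (1/n) Σ_T dbAᵢ,T     (average over the n-motif ensemble)
```

assigned to the window centre. Downstream, 100 bp marker tracks are
normalised to Z-scores, contact matrices are Z-scored, bin pairs with Z > 0
are *detected* interactions, marker enrichment per detected pair is a
rank-sum Z against 100 random pairs, and per 250 kb bin the frequencies
`Fᵢ = Nvᵢ/Nt` (detected interactions) and `F_he = Neᵢ/Nt` (highly enriched,
Z ≥ 3) feed a k-means + Gaussian-mixture clustering whose three clusters,
ranked by mean Fᵢ, are the zone types I/II/III.

## Worked example

```python
import numpy as np
from ntba import FixtureSpec, gen_motifs, gen_sequence, ntba_scan, to_energy

spec = FixtureSpec(seed=1)                      # 5 kb sequence, 12 planted sites
motifs = [to_energy(m) for m in gen_motifs(spec)]
seq, manifest = gen_sequence(spec)
profile = ntba_scan(seq, motifs, seed=1)        # mu = 0 and mu = -10
peak = profile.positions[np.nanargmax(profile.values[:, 0])]
print(len(profile.positions), peak, round(float(np.nanmax(profile.values[:, 0])), 3))
```

prints

```
991 2560 0.405
```

991 windows cover the 5 kb sequence; the profile maximum (nTBA ≈ 0.41 at
μ = 0) sits at position 2560, inside the planted motif cluster centred at
2500 — the scanner localises the cluster without being told where it is. At
μ = −10 the same profile's maximum magnitude drops to ~4 × 10⁻⁵: nonspecific
affinity vanishes as the chemical potential becomes strongly negative.

The same workflow from the shell:

```bash
ntba all --seed 1 --out run1        # simulate + scan + profile + tracks
                                    # + hic-enrich + zones
cut -f4 run1/zones.tsv | sort | uniq -c
```

## Layout

| module | contents |
| --- | --- |
| `ntba.motifs` | JASPAR/plain motif parsing, PWM → binding-energy matrices |
| `ntba.engine` | sliding-window grid, binding probabilities, dbA, `ntba_scan` |
| `ntba.features` | 1000 bp feature windows, profile aggregation, overlap tables, core bins |
| `ntba.tracks` | 100 bp coverage binning, Z-score normalisation |
| `ntba.hic` | contact-matrix Z-scores, rank-sum enrichment, Fᵢ / F_he |
| `ntba.zones` | stress curve, k-means + GMM clustering, zone labelling |
| `ntba.fixtures` | seeded synthetic generators with planted ground truth |
| `ntba.pipeline`, `ntba.cli` | stage orchestration and the `ntba` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
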