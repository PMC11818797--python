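# plmnet

Source-level brain-network analysis for two-group electrophysiology
studies: band-limited **phase linearity measurement (PLM)** connectivity,
**eigenvector centrality (EC)** with lobe-level aggregation, and
**permutation-based group statistics** with Benjamini–Hochberg FDR
control — plus a synthetic-cohort generator with planted, recoverable
network effects, so every stage of the pipeline can be verified without
access to patient recordings.

The package is aimed at researchers analysing source-reconstructed
MEG/EEG region time series (e.g. a Parkinson's-disease cohort against
matched healthy controls), and at methodologists who want a tested,
deterministic reference implementation of the PLM → EC → permutation
chain.

## The method

Starting from per-subject region × time source signals (90 regions of the
AAL atlas after cerebellar exclusion):

1. **Band decomposition.** Zero-phase 4th-order Butterworth band-pass
   into delta (0.5–4 Hz), theta (4–8), alpha (8–13), beta (13–30) and
   gamma (30–48).
2. **Phase extraction.** Instantaneous phase φᵢ(t) from the analytic
   signal of each band-limited channel.
3. **PLM connectivity.** For each region pair, form the interferometric
   signal z(t) = exp(i·(φᵢ − φⱼ)) and compute the fraction of its
   spectral energy within |f| ≤ B (B = 1 Hz):

       PLM = Σ_{|f| ≤ B} |S_z(f)|² / Σ_f |S_z(f)|²  ∈ [0, 1],

   with the f = 0 bin discarded, which makes the metric insensitive to
   instantaneous signal mixing (volume conduction).
4. **Eigenvector centrality.** For each subject's connectivity matrix
   A = (aᵢⱼ), solve A x = λ x for the leading eigenvalue; the
   Perron–Frobenius eigenvector, normalized to Σᵢ x̃ᵢ² = 1, scores each
   region by the quantity and quality of its connections.
5. **Lobe aggregation.** Region scores are averaged within six groups:
   frontal, insular, temporal, parietal, occipital, subcortical.
6. **Statistics.** Per band and lobe, a permutation test on the absolute
   difference of group means (50,000 shuffles, exact enumeration when
   feasible), BH-FDR corrected across the six lobes within each band;
   Pearson correlations of lobe EC against clinical scores (UPDRS-III,
   disease duration) within the patient group.

## Worked example

A reduced synthetic cohort (12 + 12 subjects, 12 regions, alpha-band
carrier) with a coupling increase planted in the two frontal regions of
the PD-like group:

```python
from plmnet import CohortSpec, LobeCentralityModel, generate_cohort, band_by_name
from plmnet.atlas import LobePartition, LOBE_GROUPS
from plmnet.pipeline import subject_lobe_table

labels = tuple(f"r{i}" for i in range(12))
partition = LobePartition({f"r{i}": g for i, g in enumerate(
    [g for g in LOBE_GROUPS for _ in range(2)])})
spec = CohortSpec(n_pd=12, n_hc=12, n_regions=12, region_labels=labels,
                  hub_regions=frozenset({"r0", "r1"}), fs=128, duration_s=20,
                  seed=7)
cohort, signals = generate_cohort(spec)
sig_map = dict(zip(cohort["subject_id"], signals))
_, lobe_table = subject_lobe_table(sig_map, partition,
                                   bands=(band_by_name("alpha"),))
res = LobeCentralityModel(lobe_table, cohort).fit(n_perm=5000, seed=7)
print(res.summary())
```

```
Lobe eigenvector-centrality group comparison
====================================================
permutations per test: 5000   FDR q: 0.05   seed: 7

 band        lobe   stat  p_raw  p_fdr direction  n_a  n_b sig
alpha     frontal 0.0592 0.0002 0.0012 PD_higher   12   12   *
alpha     insular 0.0092 0.0846 0.1015 HC_higher   12   12
alpha    temporal 0.0130 0.0250 0.0375 HC_higher   12   12   *
alpha    parietal 0.0108 0.1038 0.1038 HC_higher   12   12
alpha   occipital 0.0232 0.0008 0.0024 HC_higher   12   12   *
alpha subcortical 0.0116 0.0156 0.0312 HC_higher   12   12   *

Correlations with clinical scores (PD group)
----------------------------------------------------
 band        lobe         variable       r  p_raw  p_fdr  n sig
alpha     frontal           updrs3  0.8643 0.0003 0.0006 12   *
alpha     frontal disease_duration  0.4922 0.1041 0.1387 12
...
```

Reading the output: the planted frontal hub strengthening is recovered
(`frontal`, `PD_higher`, p_FDR ≪ 0.05), and because EC scores are
unit-normalized per subject, the frontal increase is mirrored by
compensatory decreases elsewhere (the `HC_higher` rows). The pseudo
UPDRS-III score, generated to track the planted effect, correlates
positively with frontal alpha EC (r = 0.86 in this small cohort).

The same analysis runs from the shell:

```bash
plmnet simulate --n-pd 12 --n-hc 12 --duration 20 --fs 128 --out sim/
plmnet connectivity --signals sim/signals --cohort sim/cohort.csv --band alpha --out conn/
plmnet stats --lobes conn/ec_lobes.csv --cohort sim/cohort.csv --seed 7 --out stats/
# or everything at once from a YAML config:
plmnet run-all --config pipeline.yaml
```

## Layout

- `plmnet.simulate` — synthetic cohorts (coupled-phase generative model)
- `plmnet.signal` — band-pass filtering, band decomposition, phase
- `plmnet.plm` — PLM pairs and matrices
- `plmnet.atlas` / `plmnet.centrality` — AAL labels, ROI filter, EC, lobes
- `plmnet.stats` — permutation test, BH-FDR, correlations
- `plmnet.model` — `LobeCentralityModel` / `LobeCentralityResults`
- `plmnet.pipeline` / `plmnet.cli` — config-driven runs, manifests, CLI

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
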