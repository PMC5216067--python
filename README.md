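# pcsassign

Sequence-specific assignment of protein methyl resonances from
lanthanide-induced pseudocontact shifts (PCSs).

Methyl-TROSY (¹H-¹³C HMQC) spectra of ²H,¹³CH₃-ILMV-labeled proteins stay
sharp even for very large or poorly soluble complexes, but the cross-peaks
are useless without assignments, and triple-resonance walks often fail for
exactly those systems. When a structure is known, a paramagnetic lanthanide
tag offers a shortcut: it shifts every nucleus by a pseudocontact shift

    PCS(ppm) = 1e4/(12π r³) · [Δχ_ax (3cos²θ − 1) + (3/2) Δχ_rh sin²θ cos2φ]

that depends only on the nucleus' position (r, θ, φ) relative to the tag's
anisotropic susceptibility tensor Δχ. Measure PCSs as tagged-minus-untagged
shift differences, fit the Δχ tensor against the structure, predict the PCS
of every methyl, and match predictions to peaks — iterating as the growing
assignment set sharpens the tensors. `pcsassign` implements this whole
pipeline for multi-subunit complexes labeled one subunit at a time, with
several tag sites and lanthanides (e.g. strongly shifting/broadening Dy³⁺
plus weakly shifting/broadening Yb³⁺) fit jointly, peaks broadened away near
the metal handled as evidence rather than loss, and a ground-truthed
synthetic-data generator for validation. It is aimed at NMR spectroscopists
and method developers working on large complexes where only 2D methyl
spectra are practical.

## Worked example

Simulate a four-helix-bundle study (two Dy³⁺ sites, one Yb³⁺ site,
stereospecific companion samples), then assign it:

```bash
pcsassign simulate --seed 1 --out run1
# ... writes run1/structure.pdb, per-dataset peak lists, ground truth

pcsassign assign --config run1/run.yaml --seed 1 --out run1/assigned
```

(The test suite builds `run.yaml` automatically; it lists the structure and
one entry per dataset with its tag site, lanthanide, labeled subunit, nuclei
and peak-list files.) The assign step prints, for example:

```
converged=True iteration=4 unambiguous=35 tentative=61
```

meaning the loop reached a fixed point after four rounds and assigned 96
cross-peaks, 35 of them graded unambiguous (large cost margin, supported by
at least two datasets, plausible fit, extra caution near the tags and in the
Leu/Val overlap region) and the rest tentative. `run1/assigned/` then holds
`assignments.tsv` (subunit, residue, methyl, stereo label, shifts, status,
margin per peak), `tensors.txt` (fitted Δχ_ax, Δχ_rh, metal position and
axes per tag-site/lanthanide group, in the unique tensor representation),
one NPC-format PCS list per group, and `fit_stats.tsv` with per-group Q,
slope and intercept (here: Q 0.23/0.02/0.15, slopes 0.998-1.017, intercepts
within 0.004 ppm of zero). `pcsassign report run1/assigned` re-summarizes
any completed run directory from those files.

From Python the same pipeline is three calls:

```python
from pcsassign import SimulationConfig, simulate_run, AssignConfig, iterate

run = simulate_run(SimulationConfig(seed=1))
state, fits = iterate(run.datasets, run.methyls, AssignConfig(),
                      tag_positions=run.tag_positions,
                      free_reference=run.free_reference)
print(state.counts())            # {'unambiguous': 34, 'tentative': 62}
print(fits[('B:12', 'Dy')].q)    # 0.227: rms misfit over rms measured PCS
```

Typical fitted-tensor quality on these simulations: Q ≈ 0.1, observed-vs-
calculated slope ≈ 1.00, intercept ≈ 0 ppm, axial anisotropies recovered to
a few tenths of 10⁻³² m³.

## Layout

- `src/pcsassign/structure.py` — PDB parsing, ILMV methyl extraction,
  stereo conventions
- `src/pcsassign/tensor.py` — Δχ tensors, the PCS forward model, UTR
- `src/pcsassign/peaks.py` — peak lists, diagonal-cost pairing, PCS
  measurement, NPC interchange
- `src/pcsassign/fit.py` — variable-projection tensor fitting, Q/slope/
  intercept diagnostics, Monte-Carlo errors, leave-one-out
- `src/pcsassign/assign.py` — seeding, metal-grid tensor bootstrap, direct
  spectral-evidence matching, classification, the iterative loop
- `src/pcsassign/simulate.py` — synthetic bundles, tensors and peak lists
  with ground truth
- `src/pcsassign/cli.py`, `config.py` — the `pcsassign` command and YAML
  run configuration

`docs/methods.md` documents the model, parameters and design decisions in
detail.
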