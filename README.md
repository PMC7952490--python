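# ludose

Voxel-level dosimetry for Lu-177 radioligand therapy of skeletal
metastases, built to quantify how the choice of dosimetry method biases
bone-lesion absorbed dose estimates.

Patients with metastatic castration-resistant prostate cancer treated with
Lu-177-PSMA carry many osteosclerotic bone lesions whose mass density
(≈ 0.8–1.7 g/cm³) departs strongly from the unit-density soft tissue
assumed by the standard clinical dose models. `ludose` implements the
whole comparison chain on synthetic SPECT/CT-like phantoms:

* **MC** — a voxel Monte Carlo reference on the patient density grid
  (Lu-177 betas, conversion/Auger electrons and photons; CSDA electron
  tracks, ray-traced photons with Klein–Nishina scattering; per-voxel
  batch uncertainty);
* **TSV / TSV_weighted** — the unit-density sphere-model tumor S value
  `S(m) = 2.19·10⁻⁵ · m^(−0.99)` Gy/(MBq·s), optionally mass-scaled by
  `1 g/cm³ / ρ̄_lesion` (the lesion's mean CT density);
* **VSV^soft, VSV^soft+bone** — convolution of the time-integrated
  activity (TIA) image with 51³ voxel-S-value kernels simulated for ICRP
  soft tissue and cortical bone, the composite applying each kernel in its
  CT region (bone map = HU ≥ 200);
* **weighted VSV variants** — voxel-wise density weighting
  `D · ρ_kernel / ρ_voxel` from the Schneider-style HU→density curve.

Upstream, VOI time–activity curves from 24/48/72 h images are fitted
mono-exponentially (`λ_VOI = ln2 / t_eff`) and turned into a hybrid
VOI/voxel TIA image `Ã = A_t e^(λt) / λ`; downstream, methods are compared
against MC by per-lesion percentage differences (`PD^av`, `PD^vox`),
DVH percentiles D25/D50/D75 and Bland–Altman limits of agreement.

## Worked example

Run the full synthetic-cohort comparison (30 bone lesions with volumes
log-normal around 19.1 ml and densities ~N(1.25, 0.11) g/cm³, Monte Carlo
reference at 2·10⁶ histories per phantom):

```python
from ludose.pipeline import PipelineConfig, run_cohort

cfg = PipelineConfig(n_lesions=30, mc_primaries=2_000_000, seed=1)
result = run_cohort(cfg)
for key in ("pd_av_tsv", "pd_av_tsv_w", "pd_vox_vsv_soft",
            "pd_vox_vsv_soft_w", "pd_vox_vsv_sb", "pd_vox_vsv_sb_w"):
    s = result.summary[key]
    print(f"{key:22s} {s['mean']:+6.1f} ± {s['sd']:.1f} %")
```

prints (cohort mean ± SD across lesions):

```
pd_av_tsv               +18.2 ± 10.7 %
pd_av_tsv_w              -4.6 ± 0.9 %
pd_vox_vsv_soft         +22.4 ± 10.9 %
pd_vox_vsv_soft_w        -1.2 ± 1.1 %
pd_vox_vsv_sb           -21.3 ± 8.6 %
pd_vox_vsv_sb_w          +1.2 ± 0.9 %
```

i.e. the unit-density sphere model and the soft-tissue kernel overestimate
lesion dose by roughly the lesion density excess, the pure cortical-bone
composite underestimates it, and density weighting collapses both biases
to a few percent — the method ranking observed clinically.

The same experiment is available from the shell
(`ludose run --out report/ --n-lesions 30 --seed 1`), and the individual
stages as `ludose phantom | segment | tia | kernel | mc | dose | compare`.

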