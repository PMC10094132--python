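"""Quantify a 3-field biopsy: spectra, emission peak, 78-ROI summary.

Simulates a severe-dystrophy (DMD) biopsy at the published NCL-Dys1 level
(500.8 a.u.), detects 26 ROIs per field automatically, extracts each ROI's
spectral signature, selects the maximum emission peak on the pooled mean
spectrum, and reports the biopsy mean +/- SE over the 78 ROIs.
"""

from dysquant.quantify import detection_percentage
from dysquant.simulate import (
    GroupSpec,
    generate_cohort,
    group_intensity_params,
    reference_spectrin_params,
)
from dysquant.workflow import PipelineConfig, quantify_biopsy

spec = GroupSpec(
    group_label="DMD",
    n_biopsies=1,
    channel_params={
        "beta-spectrin": reference_spectrin_params("DMD"),
        "NCL-Dys1": group_intensity_params("DMD", 500.8, 17.6),
    },
    between_biopsy_frac=0.0,
)
cfg = PipelineConfig(seed=3)
(biopsy,) = generate_cohort([spec], fields_per_biopsy=3, seed=3,
                            confounder_fracs=cfg.confounder_fracs)

results, roisets = quantify_biopsy(biopsy, cfg, roi_mode="auto")
res = results["NCL-Dys1"]
print(f"{res.biopsy_id}: n={res.n_rois} ROIs over {len(roisets)} fields")
print(f"emission peak at {res.peak_center_nm:.1f} nm ({res.peak_policy})")
print(f"dystrophin: {res.mean_intensity:.1f} ± {res.se_intensity:.1f} a.u. "
      f"(generated at {biopsy.true_means['NCL-Dys1']:.1f})")

pct = detection_percentage(res.mean_intensity, 2982.9)
print(f"as a percentage of the control level: {pct}%")
# A trace as low as 15 a.u. (0.5% of the control mean) is still quantifiable
# by this spectral approach; see detection_percentage(15, 2982.9).
#
# Note: the ROI-level SE understates biopsy-level uncertainty — ROIs placed
# on the same fibre share that fibre's membrane intensity, so a single
# biopsy's recovered mean scatters around the generating level with the
# between-fibre spread, not SE/sqrt(78).
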