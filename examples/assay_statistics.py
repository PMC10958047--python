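"""Call activity from synthetic assay plates with known ground truth.

Generates morphological-fingerprint, growth-curve and MTT plates with
planted actives, then runs the package's assay statistics: the
5x-negative-control activity threshold, MIC reading from OD600 growth
curves, and background-subtracted percent viability.
"""

import numpy as np

from tsnap import (
    active_concentrations,
    activity_score,
    dilution_series,
    mic_from_curves,
    mtt_viability,
)
from tsnap.fixtures import FixtureSpec, synth_assay_plates

series = dilution_series(128.0, 16, 2.0)
print(f"dilution series: {series.describe()}")

spec = FixtureSpec(seed=2, effect_size=10.0, planted_mic_step=7)
plates = synth_assay_plates(spec)
truth = plates["truth"]
fp = plates["fingerprints"]
features = [c for c in fp.columns if c.startswith("f")]
negatives = fp[fp.is_negative_control][features].apply(activity_score, axis=1).values
print(f"\nnegative-control activity scores: mean {negatives.mean():.2f} "
      f"(threshold = 5x = {5 * negatives.mean():.2f})")

print(f"\n{'compound':9s} {'min active uM':>14s} {'MIC':>10s} {'viability %':>12s}")
mtt = plates["mtt"]
background = mtt[mtt.role == "mtt_only"].absorbance.values
dmso = mtt[mtt.role == "vehicle"].absorbance.values
for cpd in truth["mic_uM"]:
    sub = fp[fp.compound == cpd]
    scores = {conc: g[features].apply(activity_score, axis=1).mean()
              for conc, g in sub.groupby("concentration_uM")}
    call = active_concentrations(scores, negatives)
    mic = mic_from_curves(plates["growth"][plates["growth"].compound == cpd])
    treated = mtt[(mtt.compound == cpd) & (mtt.role == "treatment")].absorbance
    viability = np.mean([mtt_viability(a, background, dmso) for a in treated])
    print(f"{cpd:9s} {str(call):>14s} {str(mic):>10s} {viability:12.1f}")
print("\nplanted truth:", {k: truth[k] for k in ('active_compounds', 'mic_uM')})
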