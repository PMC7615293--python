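"""Identity-vs-activity calibration: how often do high-identity pairs cross-react?

Simulates two synthetase families and an activity matrix in which
combinations of entities sharing more than 55% identity are active with
probability 0.9, then recovers that rate from the assembled
(identity, activity) points — the analysis that motivates using 55%
sequence identity as an orthogonality screening threshold.
"""

import pylortho as po

aln, truth = po.simulate_sequence_classes(
    2, [12, 12], intra_identity_min=70, inter_identity_max=40, seed=42
)
ident = po.identity_matrix(aln)
activity, _ = po.simulate_activity_matrix(
    ident, identity_threshold=55.0, p_active_high=0.9, seed=42
)

synth_ident = po.IdentityMatrix(
    tuple(f"{e}_RS" for e in ident.ids), ident.values
)
cognates = {f"{e}_tRNA": f"{e}_RS" for e in ident.ids}
points = po.build_identity_activity_points(
    activity, synth_ident, None, cognates, axis="synthetase"
)
print(f"{len(points)} measured combinations")

curve = po.scan_thresholds(points, activity_cutoff=40.0, grid=[30, 45, 55, 65])
for t, f, n in zip(curve.thresholds, curve.fractions, curve.n_above):
    shown = "undefined" if f is None else f"{100 * f:.1f}%"
    print(f"  identity > {t:2.0f}%: {shown} of {n} combinations active")

res = po.fraction_active_above(points, 55.0, 40.0)
print(
    f"\nAbove the 55% identity threshold, {100 * res.fraction:.1f}% of\n"
    f"combinations are active ({res.n_active}/{res.n_above}); the generator's\n"
    "true above-threshold activation rate is 90%, so the estimate recovers\n"
    "the planted parameter within binomial error."
)
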