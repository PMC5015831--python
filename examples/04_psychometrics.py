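"""Fit a probit psychometric function to simulated 2AFC discrimination data.

An observer with sensory uncertainty sigma judges which of two cursors is
further along the perturbation axis; offsets span [0, ±0.7, ±1.4, ±2.1] mm
with 20 presentations each.  The fitted sigma estimates the visual
uncertainty of localising the endpoint cursor.
"""

from motorlearn import fit_probit, generate_2afc, predict_prob

sigma_true = 1.63   # mm, localisation uncertainty of a deep target
table = generate_2afc(sigma_true, mu_true=0.0, seed=5)
print(f"{len(table)} trials ({table.offset_mm.nunique()} offsets x 20 repetitions)")

fit = fit_probit(table.offset_mm, table.response)
print(f"fitted mu    = {fit.mu:+.3f} mm  (point of subjective equality)")
print(f"fitted sigma = {fit.sigma:.3f} mm  (true {sigma_true})")
for d in (-2.1, 0.0, 2.1):
    print(f"  P(respond positive | offset {d:+.1f} mm) = {predict_prob(fit, [d])[0]:.3f}")
# sigma is the slope scale of the psychometric curve: smaller sigma means a
# steeper curve and a more reliable visual error signal.
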