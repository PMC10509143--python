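"""Bland-Altman agreement between predicted and actual Hb loss.

Simulates a predictor with a small systematic bias and random error,
then summarizes agreement as bias +/- 1.96*SD limits with 95% CIs, and
renders the classic difference-vs-mean plot.
"""

from pathlib import Path

import numpy as np

from spongehb import bland_altman
from spongehb.evaluation import bland_altman_plot

rng = np.random.default_rng(0)
actual = rng.uniform(20, 500, 256)
predicted = actual + rng.normal(2.0, 12.0, actual.size)  # bias 2 mg, SD 12 mg

rep = bland_altman(predicted, actual)
print(f"n = {rep.n} sponge pairs")
print(f"bias       {rep.bias:7.2f} mg  (95% CI {rep.ci_bias[0]:.2f}, {rep.ci_bias[1]:.2f})")
print(f"lower LOA  {rep.loa_lower:7.2f} mg  (95% CI {rep.ci_loa_lower[0]:.2f}, {rep.ci_loa_lower[1]:.2f})")
print(f"upper LOA  {rep.loa_upper:7.2f} mg  (95% CI {rep.ci_loa_upper[0]:.2f}, {rep.ci_loa_upper[1]:.2f})")
print(
    "\n~95% of per-sponge prediction errors fall between the LOA; the LOA "
    "are symmetric about the bias (lower + upper = 2 x bias)."
)

out = Path("scratch/bland_altman.png")
out.parent.mkdir(exist_ok=True)
bland_altman_plot(predicted, actual, out, report=rep)
print(f"plot written to {out}")
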