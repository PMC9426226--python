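"""Observe true reliability from a truth-labeled session.

When the true category of every item is known, reliability need not be
estimated: agreement splits into agree-and-right and agree-and-wrong,
the true chance agreement is twice the wrong agreement (guessing between
two confusable categories lands on the truth half the time), and
o_ri = a_o − o_ac is the golden standard the indices try to estimate.
"""

from agreebench import observe, threshold
from agreebench.simulate import (
    BehaviorModel,
    DesignCell,
    simulate_session,
)

cell = DesignCell(n_categories=2, skew=0.75, difficulty=1.0, n_items=100)
model = BehaviorModel(guess_rate=lambda d: 0.87 * d)  # hard task: 87% guessing
session = simulate_session(cell, model, seed=42)
gs = observe(session)

print(f"agree-and-right  o_ar = {gs.o_ar:.2f}")
print(f"agree-and-wrong  o_ae = {gs.o_ae:.2f}")
print(f"observed agreement a_o = {gs.a_o:.2f}")
print(f"true chance agreement o_ac = 2*o_ae = {gs.o_ac:.2f}")
print(f"true reliability o_ri = a_o - o_ac = {gs.o_ri:.2f}")
print(f"accuracy threshold t_h = o_ac/(1-o_ri) = {gs.t_h:.3f}")

# The threshold is the chance estimate a perfect index would need: an
# index whose a_c equals t_h reproduces o_ri exactly through the common
# correction; a_c above t_h underestimates reliability, below it
# overestimates.  Note t_h > o_ac whenever o_ri > 0 — an index cannot be
# exact on chance agreement and reliability at the same time.
print(f"grand-mean plug-in: t_h(o_ac=.13, o_ri=.555) = "
      f"{threshold(0.13, 0.555):.3f}")
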