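"""Compute the behavioral summary statistics for a simulated session.

Simulates a low-noise session, canonicalizes rotation order, and prints the
reinforcement rate, early learning slope, total learning, and the mean
absolute trial-to-trial reach change split by the four feedback-by-accuracy
categories.
"""
from reachrl import AgentParams, condition_preset, simulate_session, summarize_session

agent = AgentParams(sigma_m=3.5, sigma_e_rewarded=1.5, sigma_e_unrewarded=3.0)
session = simulate_session(condition_preset("low-noise"), agent, seed=8)
summary = summarize_session(session)

print(f"reinforcement rate: {summary.reinforcement_rate:.1f} %")
for block in ("R1", "R2"):
    print(f"{block}: early slope {summary.early_learning_slope[block]:.3f} deg/trial, "
          f"total learning {summary.total_learning[block]:.1f} deg")
print("\nmean |reach change| after each feedback type:")
for label, value in summary.delta_by_category.items():
    count = summary.category_counts[label]
    shown = "  (empty)" if value is None else f"{value:5.2f} deg"
    print(f"  {label:>20}: {shown}  n={count}")

# A positive slope/total learning means the reach moved to counter the
# rotation. Changes after unrewarded trials exceed those after rewarded
# trials because the agent explores more after failure; external noise
# creates the two mismatch categories (rewarded-out, unrewarded-in).
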