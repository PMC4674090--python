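"""Simulate the operant-conflict game with decision-theoretic agents.

Builds agents that plan every approach by maximising expected utility under
the example threat prior, runs a small cohort through the token-collection
game, and prints the structure of the resulting trial table.
"""

import numpy as np

import conflictbdt as cb

config = cb.TaskConfig()  # 270 epochs, 6 tokens, catch p = 0.1/0.2/0.3 per 100 ms
print("threat activation rates (1/s):", [round(r, 4) for r in config.threat_rates])

agent = cb.make_bdt_agent(
    cb.example_threat_prior(),
    cb.UtilityParams(gain=1.0, loss=-1.0),
    cb.GainPrior(rate=1.0 / config.token_lifetime_mean),
    noise_sd=0.05,
)
trials = cb.simulate_experiment(config, agent, n_subjects=6, seed=42)
print(f"\n{len(trials)} token opportunities from 6 subjects x {config.n_epochs} epochs")
print(trials.head(8).to_string(index=False))

go = trials[trials.went]
print(f"\ngo rate: {trials.went.mean():.2f}; caught on {go.caught.mean():.3f} of movements")
print("\nmean approach latency (s) by threat level x tokens at stake:")
pivot = go[go.potential_loss.between(1, 3)].pivot_table(
    values="approach_latency", index="potential_loss", columns="threat_level_index"
)
print(pivot.round(3).to_string())
print("\n-> latency rises along both axes: the simulated agents show the")
print("   anxiety-like behavioural inhibition the decision model prescribes.")
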