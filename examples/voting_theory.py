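"""Why majority voting of three independent classifiers wins.

For equal accuracies q in (0.5, 1) the majority vote achieves 3q^2 - 2q^3,
which strictly exceeds q. The simulation draws independent Bernoulli voters
and should land within a few binomial standard errors of the closed form.
"""

from m6avote import VotingScenario, simulate_voting, voting_accuracy_closed_form

for q in (0.55, 0.6, 0.7, 0.8, 0.9):
    s = VotingScenario(q, q, q)
    closed = voting_accuracy_closed_form(s)
    emp = simulate_voting(s, 100_000, seed=0)
    print(f"q={q:.2f}  closed form={closed:.4f}  simulated={emp:.4f}  gain={closed - q:+.4f}")

s = VotingScenario(0.65, 0.72, 0.78)
print(
    f"\nunequal voters {s.ps}: ensemble={voting_accuracy_closed_form(s):.4f}, "
    f"best single={max(s.ps):.2f}"
)
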