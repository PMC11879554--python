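"""Call differentially accumulated metabolites from a two-group table.

Computes PLS-DA VIP scores on the leaf-vs-root contrast and applies the
DAM thresholds: VIP >= 1, |log2FC| >= 1, Welch P < 0.05.
"""

from asekit import metabolome
from asekit.simulate import GroundTruth, SimulationConfig, simulate_metabolome

config = SimulationConfig(seed=7)
truth = GroundTruth({}, {"HA": [], "HB": []}, {}, {}, {})
intensities, groups = simulate_metabolome(config, truth)

vip = metabolome.plsda_vip(intensities, groups)
calls, summary = metabolome.call_dams(intensities, groups, vip)
print(f"metabolites: {summary['n_total']}  "
      f"up: {summary['n_up']}  down: {summary['n_down']}")

planted_up = sum(1 for s in truth.planted_dams.values() if s == "up")
recovered = sum(
    1 for m, s in truth.planted_dams.items()
    if s == "up" and calls.loc[m, "status"] == "up"
)
print(f"planted up: {planted_up}, recovered as up: {recovered}")
print(calls.sort_values("vip", ascending=False).head(5).round(3))
# With a planted 3-unit log2 shift and 0.3 noise SD the thresholds
# recover essentially all planted DAMs; VIP concentrates on them.
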