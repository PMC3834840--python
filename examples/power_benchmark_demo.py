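"""A scaled-down power benchmark contrasting two signal regimes.

For a (50, 50) design, measures power (fraction of reporter genes detected at
an empirical-null false-positive rate alpha) for DIDS-tanh, DIDS-quad, MOST
and the Welch t-test in two regimes: a small aberrant subgroup with a strong
shift, and a large aberrant subgroup with a weak shift. Reporter genes only
are simulated; thresholds come from a separate run of 20 000 null genes.
"""

from dids.simulation import METHODS, SimulationConfig, power_surface, simulate_null_genes

cfg = SimulationConfig(n1=50, n2=50, seed=5)
null_c, null_b = simulate_null_genes(cfg, 20_000)

print(f"{'method':>10} {'Δ=4, p_a=5%, α=0.01':>22} {'Δ=1, p_a=35%, α=0.05':>22}")
for method in ("dids-tanh", "dids-quad", "most", "ttest-uv"):
    surface = power_surface(
        method, cfg, deltas=[1.0, 4.0], pa_grid=[0.05, 0.35],
        alpha_grid=[0.01, 0.05], n_reporters=300,
        null_scores=METHODS[method](null_c, null_b),
    )
    t = surface.table.set_index(["delta", "p_a", "alpha"])["value"]
    print(f"{method:>10} {t[(4.0, 0.05, 0.01)]:>22.3f} {t[(1.0, 0.35, 0.05)]:>22.3f}")

print("\nLeft column: 3 of 50 cases shifted by 4 SD — the quadratic scoring")
print("function shines because it rewards a few large excesses. Right column:")
print("18 of 50 cases shifted by 1 SD — a diluted mean shift that group-wise")
print("tests pick up at permissive alpha.")
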