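"""Estimate a gap-junction coupling coefficient from paired current-clamp sweeps.

Simulates a bidirectional paired recording (hyperpolarizing steps into each
cell in turn, 60 sweeps/direction, 0.1 mV sample noise) with a true coupling
coefficient of 0.025 — the weak electrotonic coupling typical of connexin-36
junctions — and recovers it from the steady-state deflection ratio.
"""

from pitsync import estimate_coupling, simulate_paired_experiment


def main() -> None:
    sweeps_12, sweeps_21 = simulate_paired_experiment(
        true_cc=0.025, n_sweeps=60, noise_sd_mv=0.1, seed=4
    )
    est = estimate_coupling(sweeps_12, sweeps_21)
    print(f"cell1 -> cell2: cc = {est.cc_12:.4f} +/- {est.sem_12:.4f} (SEM)")
    print(f"cell2 -> cell1: cc = {est.cc_21:.4f} +/- {est.sem_21:.4f} (SEM)")
    print(f"mean coupling coefficient = {est.mean_cc:.4f} over {est.n_sweeps} sweeps")
    print(f"classified as coupled (cc > 3 SEM both ways): {est.coupled}")
    print(
        "\nA cc of ~0.025 means the follower cell sees 2.5% of the injected "
        "cell's steady-state voltage deflection."
    )


if __name__ == "__main__":
    main()
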