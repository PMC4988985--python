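"""Simulate a coupled and an uncoupled gonadotrope arm and compare synchrony.

Builds 7 replicate slice experiments per arm (~60 cells each), detects GnRH
responders, computes all-pairs Spearman coefficients in the canonical
before/during/after windows, and runs the between-arm Mann–Whitney test.
A gap-junction-coupled network should show a higher during-window median
while the pre-stimulus windows stay indistinguishable.
"""

from pitsync import SimulationConfig, compare_groups
from pitsync.pipeline import PipelineConfig, analyze_dataset, simulate_group


def pooled(coupled: bool, seed: int, cfg: PipelineConfig) -> dict:
    base = SimulationConfig(coupling_enabled=coupled)
    pooled = {name: [] for name, _, _ in cfg.windows}
    for ds in simulate_group(base, 7, "arm", seed):
        per = analyze_dataset(ds, cfg, group="coupled" if coupled else "uncoupled")
        for name in pooled:
            pooled[name].extend(per[name])
    return pooled


def main() -> None:
    cfg = PipelineConfig()
    pairs_c = pooled(True, seed=11, cfg=cfg)
    pairs_u = pooled(False, seed=22, cfg=cfg)
    print("window   n_coupled n_uncoupled median_c median_u  Mann-Whitney p")
    for window in ("before", "during", "after"):
        c = compare_groups(pairs_c[window], pairs_u[window], window=window)
        print(
            f"{window:<8} {c.n_a:>9} {c.n_b:>11} {c.median_a:>8.3f} "
            f"{c.median_b:>8.3f}  {c.p_value:.3g}"
        )
    print(
        "\nHigher coupled median during stimulation = gap-junction-mediated "
        "synchrony; similar 'before' medians = no baseline difference."
    )


if __name__ == "__main__":
    main()
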