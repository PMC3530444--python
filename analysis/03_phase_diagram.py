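#!/usr/bin/env python
"""Phase map of compaction vs the two free interfacial coefficients.

Sweeps a small grid over the SGP-SGP coefficient (adhesion when negative)
and the SGP-medium tension, recording the windowed mean gonad circularity
per grid point. With the default literal energy units the map is nearly
flat (kinetically arrested; see docs/methods.md); with --sgp-units the
surface becomes thermally active and the tension axis resolves.
Writes results/phase_trials.csv, phase_means.csv and phase_diagram.png.
"""

import argparse
from dataclasses import replace
from pathlib import Path

from gonadcpm import phase_sweep, preset_config
from gonadcpm.cli import _plot_phase_diagram

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-trials", type=int, default=2)
    parser.add_argument("--n-mcs", type=int, default=8000)
    parser.add_argument("--sgp-units", action="store_true")
    args = parser.parse_args()

    config, _ = preset_config("movie-s4-reduced")
    if args.sgp_units:
        config = replace(config, sgp_energy_unit="sgp")
    diagram = phase_sweep(
        config,
        e_sgp_sgp_values=[-0.02, -0.01, 0.0],
        e_sgp_out_values=[0.10, 0.16, 0.22],
        n_trials=args.n_trials,
        n_mcs=args.n_mcs,
        mcs_window=(args.n_mcs // 2 + args.n_mcs // 8, args.n_mcs),
        seed=args.seed,
    )
    suffix = "_sgp_units" if args.sgp_units else ""
    diagram.trials.to_csv(RESULTS / f"phase_trials{suffix}.csv", index=False)
    means = diagram.trials.groupby(["e_sgp_sgp", "e_sgp_out"])[
        "mean_circularity"].mean().reset_index()
    means.to_csv(RESULTS / f"phase_means{suffix}.csv", index=False)
    _plot_phase_diagram(diagram, RESULTS / f"phase_diagram{suffix}.png")
    print("windowed mean circularity per grid point:")
    for row in means.itertuples():
        print(f"  E_SGP-SGP {row.e_sgp_sgp:+.2f}, E_SGP-out {row.e_sgp_out:.2f}: "
              f"{row.mean_circularity:.3f}")


if __name__ == "__main__":
    main()
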