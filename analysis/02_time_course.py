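#!/usr/bin/env python
"""Compaction time courses at the two published interfacial settings.

Runs the reduced-lattice gonad model with the Movie S4 coefficients
(SGP-SGP adhesion on, E_SGP-SGP = -0.01) and the Movie S5 coefficients
(adhesion off, E_SGP-SGP = 0) and writes the gonad-circularity and energy
series plus a comparison figure. The default (published, literal) energy
units leave the tissue surface nearly frozen, so both settings arrest well
short of a sphere — the reproducibility limit discussed in
docs/methods.md. Passing --sgp-units runs the alternative reading with the
SGP coefficients in the SGPs' own elastic unit.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from gonadcpm import preset_config, run_gonad_simulation
from gonadcpm.io import trace_series_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--sgp-units", action="store_true",
                        help="read SGP coefficients in K_S*V_S0^1.5 units")
    args = parser.parse_args()

    frames = []
    for name in ("movie-s4-reduced", "movie-s5-reduced"):
        config, run_kwargs = preset_config(name)
        if args.sgp_units:
            config = replace(config, sgp_energy_unit="sgp")
        trace = run_gonad_simulation(
            config, n_mcs=run_kwargs["n_mcs"],
            record_every=run_kwargs["record_every"], seed=args.seed,
        )
        frame = trace_series_frame(trace)
        frame.insert(0, "preset", name)
        frames.append(frame)
        window = tuple(run_kwargs["mcs_window"])
        print(
            f"{name}: initial {trace.circularities[0]:.3f}, windowed mean "
            f"{trace.windowed_circularity(window):.3f}, final "
            f"{trace.circularities[-1]:.3f}, extinctions {len(trace.extinctions)}"
        )
    series = pd.concat(frames, ignore_index=True)
    suffix = "_sgp_units" if args.sgp_units else ""
    series.to_csv(RESULTS / f"time_course{suffix}.csv", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, sub in series.groupby("preset"):
        ax.plot(sub["mcs"], sub["gonad_circularity"], label=name)
    ax.set_xlabel("MCS")
    ax.set_ylabel("gonad circularity")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / f"time_course{suffix}.png", dpi=150)
    print(f"wrote results/time_course{suffix}.csv and .png")


if __name__ == "__main__":
    main()
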