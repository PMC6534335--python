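#!/usr/bin/env python
"""Alpha-beta amplitude-envelope correlations under spatial mixing.

Every source is built with perfectly comodulated harmonics (one 1/f
envelope scales both), yet the compound's measured alpha-beta envelope
correlation spreads out — and turns negative in a growing fraction of
instantiations — as the delay spread between sources widens.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from wavemix import run_envelope_experiment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iterations", type=int, default=200)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rep = run_envelope_experiment(
        sigmas=(0.005, 0.01, 0.02, 0.03),
        segment_lengths=(2.0, 5.0),
        n_iterations=args.iterations,
        seed=args.seed,
    )
    rep.write(out)
    s = rep.summary

    print("Alpha-beta envelope Spearman correlation by (sigma, segment length):")
    print(s.to_string(index=False))
    five = s[s["segment_length"] == 5.0].sort_values("sigma")
    print(
        "\nMedian rho falls from "
        f"{five['rho_median'].iloc[0]:.2f} at sigma = 5 ms to "
        f"{five['rho_median'].iloc[-1]:.2f} at 30 ms, with "
        f"{100 * five['fraction_negative'].iloc[-1]:.0f}% of instantiations "
        "anticorrelated — despite every constituent source being positively "
        "comodulated by construction."
    )

    fig, ax = plt.subplots(figsize=(5, 3.2))
    raw = rep.raw
    data = [
        raw[(raw.sigma == sg) & (raw.segment_length == 5.0)]["rho"].values
        for sg in (0.005, 0.01, 0.02, 0.03)
    ]
    ax.violinplot(data, positions=[5, 10, 20, 30], widths=3.5, showmedians=True)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("delay SD sigma (ms)")
    ax.set_ylabel("alpha-beta envelope rho (5 s segments)")
    fig.tight_layout()
    fig.savefig(out / "figures_envelope_rho.png", dpi=120)
    print(f"Raw/summary tables and figure written under {out}/")


if __name__ == "__main__":
    main()
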