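#!/usr/bin/env python
"""Delay mixing: harmonic attenuation versus the analytic law, ΔCT collapse.

Simulates compounds of 40 delayed sources per sigma cell, overlays the
measured coherent attenuation on exp(-2*(pi*sigma*f)^2), and tracks how
the compound's ΔCT collapses toward the sinusoidal value 0.  Also sweeps
the two-source lag circle where the cancellation is exact.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from wavemix import CanonicalWaveParams, run_attenuation_experiment, two_source_delay_sweep


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iterations", type=int, default=200)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rep = run_attenuation_experiment(n_iterations=args.iterations, seed=args.seed)
    rep.write(out)
    s = rep.summary

    sweep = two_source_delay_sweep(CanonicalWaveParams(), np.linspace(0, 0.1, 73))
    pd.DataFrame(sweep).to_csv(out / "two_source_sweep.tsv", sep="\t", index=False)

    print("Coherent attenuation vs the closed form (mean over iterations):")
    print(
        s[
            ["sigma", "coherent_alpha_mean", "analytic_alpha", "coherent_beta_mean",
             "analytic_beta", "delta_ct_median"]
        ].to_string(index=False)
    )
    worst_a = np.max(np.abs(s["coherent_alpha_mean"] - s["analytic_alpha"]))
    worst_b = np.max(np.abs(s["coherent_beta_mean"] - s["analytic_beta"]))
    print(
        f"\nLargest deviation from the analytic curve: {worst_a:.4f} (alpha), "
        f"{worst_b:.4f} (beta); the harmonic decays four times faster in the "
        "exponent and the compound ΔCT median collapses from "
        f"{s['delta_ct_median'].iloc[0]:+.3f} at zero lag toward 0."
    )

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    sig_ms = 1e3 * s["sigma"]
    axes[0].errorbar(sig_ms, s["coherent_alpha_mean"], yerr=3 * s["coherent_alpha_se"],
                     fmt="o", label="10 Hz simulated")
    axes[0].errorbar(sig_ms, s["coherent_beta_mean"], yerr=3 * s["coherent_beta_se"],
                     fmt="s", label="20 Hz simulated")
    grid = np.linspace(0, 0.031, 200)
    axes[0].plot(1e3 * grid, np.exp(-2 * (np.pi * grid * 10) ** 2), "C0--", lw=1)
    axes[0].plot(1e3 * grid, np.exp(-2 * (np.pi * grid * 20) ** 2), "C1--", lw=1)
    axes[0].set_xlabel("delay SD sigma (ms)")
    axes[0].set_ylabel("relative coherent amplitude")
    axes[0].legend(fontsize=8)
    axes[1].plot(sig_ms, s["delta_ct_median"], "o-")
    axes[1].set_xlabel("delay SD sigma (ms)")
    axes[1].set_ylabel("median compound ΔCT")
    fig.tight_layout()
    fig.savefig(out / "figures_attenuation.png", dpi=120)
    print(f"Raw/summary tables and figure written under {out}/")


if __name__ == "__main__":
    main()
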