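#!/usr/bin/env python
"""Characterize the canonical non-sinusoidal waveform and the ΔCT statistic.

Builds the two-harmonic mu-like source, tabulates its crest/trough cycles
against closed-form test signals (pure sinusoid, 30/70 duty-cycle wave),
and writes the per-cycle catalog and ΔCT summary to results/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from wavemix import (
    CanonicalWaveParams,
    TimeSeries,
    canonical_waveform,
    compute_delta_ct,
    delta_ct,
    extract_cycles,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    params = CanonicalWaveParams()
    t = np.arange(10_000) / 1000.0
    mu = TimeSeries(canonical_waveform(params, t), 1000.0, label="canonical")
    sine = TimeSeries(np.sin(2 * np.pi * 10 * t), 1000.0, label="sinusoid")
    period = np.tile(np.concatenate([np.ones(30), -np.ones(70)]), 100)
    sos = butter(4, 40.0, btype="lowpass", fs=1000.0, output="sos")
    duty = TimeSeries(sosfiltfilt(sos, period), 1000.0, label="duty 30/70")

    rows = []
    for sig in (sine, mu, duty):
        cat = extract_cycles(sig)
        est = delta_ct(cat)
        rows.append(
            {
                "signal": sig.label,
                "mean_Tc_ms": 1e3 * cat.crest_periods.mean(),
                "mean_Tt_ms": 1e3 * cat.trough_periods.mean(),
                "delta_ct": est.delta_ct,
                "n_cycles": cat.n_crests,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "waveform_shape_summary.tsv", sep="\t", index=False)
    extract_cycles(mu).to_tsv(out / "canonical_cycle_catalog.tsv")

    print("ΔCT of reference waveforms:")
    print(table.to_string(index=False))
    print(
        "\nThe sinusoid sits at ΔCT ~ 0; the canonical source spends "
        f"{table.loc[1, 'mean_Tc_ms']:.1f} ms above zero vs "
        f"{table.loc[1, 'mean_Tt_ms']:.1f} ms below (ΔCT = "
        f"{table.loc[1, 'delta_ct']:+.3f}); the 30/70 duty-cycle wave hits "
        f"{table.loc[2, 'delta_ct']:+.3f} (closed form -0.4)."
    )

    fig, axes = plt.subplots(1, 3, figsize=(11, 2.8), sharey=True)
    for ax, sig in zip(axes, (sine, mu, duty)):
        ax.plot(sig.times[:300], sig.samples[:300], lw=1.2)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(sig.label)
        ax.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out / "figures_waveforms.png", dpi=120)
    print(f"\nTables and figure written under {out}/")


if __name__ == "__main__":
    main()
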