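"""Plot a sweep summary CSV (example, not part of the API).

Usage: python examples/plot_sweep.py sweep.csv out.png
Expects a CSV produced by `culturesim sweep` with an `r` column.
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main(csv_path: str, out_path: str) -> None:
    df = pd.read_csv(csv_path)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, col, label in zip(
            axes, ["Z_max", "L_max", "T_max"],
            ["mean payoff $\\bar{Z}_{max}$",
             "mean level $\\bar{L}_{max}$",
             "distinct traits $\\bar{T}_{max}$"]):
        se = df.get("se_" + col[0])
        ax.errorbar(df["r"], df[col], yerr=se, marker="o", capsize=3)
        ax.set_xlabel("mediation ratio $r$")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
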