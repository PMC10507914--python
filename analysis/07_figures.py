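"""Render the cost-utility plane and acceptability-curve figures (PNG) from
the CSV exports of the bootstrap stage."""
import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()
    outdir = Path(args.results_dir)

    for h, label in (("d30", "30 days"), ("m3", "3 months")):
        cloud = pd.read_csv(outdir / f"cu_plane_{h}.csv")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(cloud.delta_effect, cloud.delta_cost, s=2, alpha=0.15)
        ax.axhline(0, color="k", lw=0.6)
        ax.axvline(0, color="k", lw=0.6)
        ax.set_xlabel("QALY differential (VATS - thoracotomy)")
        ax.set_ylabel("cost differential, EUR 2018")
        ax.set_title(f"Cost-utility plane, {label}")
        fig.tight_layout()
        fig.savefig(outdir / f"cu_plane_{h}.png", dpi=150)
        plt.close(fig)

        curve = pd.read_csv(outdir / f"ceac_{h}.csv")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve.wtp, curve.probability)
        ax.axvline(25_000, color="grey", ls="--", lw=0.8)
        ax.set_ylim(0, 1)
        ax.set_xlabel("willingness-to-pay, EUR per QALY")
        ax.set_ylabel("probability VATS is cost-effective")
        ax.set_title(f"Acceptability curve, {label}")
        fig.tight_layout()
        fig.savefig(outdir / f"ceac_{h}.png", dpi=150)
        plt.close(fig)
        print(f"[{h}] wrote cu_plane_{h}.png and ceac_{h}.png")


if __name__ == "__main__":
    main()
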