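#!/usr/bin/env python
"""Z-ring width, spacing and kinetics: wild-type-like vs mutant-like.

For five simulated sporulating hyphae per phenotype: average-projection +
multi-Otsu correction + midline profile + peak detection (100 AU filter),
then FWHM widths, neighbour spacings and per-ring 10x20-px ROI kinetic
traces (mean ± s.e.m. across rings). Writes ring_peaks.csv,
ring_summary.csv and ring_traces.csv under results/ and prints the
headline contrast.

Run from the repository root:  python analysis/02_ring_dynamics.py
"""

import os

import numpy as np
import pandas as pd

import septaquant as sq
from septaquant.pipeline import extract_ring_traces

RESULTS = "results"
SEEDS = {"wt_like": range(1, 6), "mutant_like": range(101, 106)}


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    all_peaks, summaries, trace_rows = [], [], []
    for name, seeds in SEEDS.items():
        per_hypha = {}
        traces = []
        for seed in seeds:
            cfg = sq.preset(name, seed=seed)
            stack, truth = sq.simulate_movie(cfg)
            midline = sq.movie_midline_trace(truth, cfg)
            res = sq.analyze_movie_rings(stack, midline)
            hid = f"{name}_s{seed}"
            per_hypha[hid] = [p for p in res.peaks]
            all_peaks.extend(
                {**vars(p), "hypha_id": hid, "genotype": name} for p in res.peaks
            )
            traces += extract_ring_traces(stack, midline, res.positions)
        summary = sq.aggregate_ring_stats(per_hypha)
        rep = summary.replicates[0]
        summaries.append(
            {
                "genotype": name,
                "mean_width_um": rep.mean_width,
                "ci95_width_um": rep.ci_width,
                "mean_spacing_um": rep.mean_spacing,
                "ci95_spacing_um": rep.ci_spacing,
                "n_rings": rep.n_rings,
                "n_hyphae": rep.n_hyphae,
                "n_censored": rep.n_censored,
            }
        )
        times, mean, sem, n = sq.mean_trace(traces, align="onset")
        for t, m, s, k in zip(times, mean, sem, n):
            trace_rows.append(
                {"genotype": name, "time_min": t, "mean_intensity": m,
                 "sem_intensity": s, "n_rings": k}
            )

    pd.DataFrame(all_peaks).to_csv(
        os.path.join(RESULTS, "ring_peaks.csv"), index=False
    )
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(os.path.join(RESULTS, "ring_summary.csv"), index=False)
    pd.DataFrame(trace_rows).to_csv(
        os.path.join(RESULTS, "ring_traces.csv"), index=False
    )

    wt = summary_df[summary_df.genotype == "wt_like"].iloc[0]
    mu = summary_df[summary_df.genotype == "mutant_like"].iloc[0]
    print(summary_df.round(3).to_string(index=False))
    print(
        f"mutant/wt mean-width ratio: {mu.mean_width_um / wt.mean_width_um:.3f} "
        f"(rings rendered 10% wider in the mutant)"
    )
    print(
        f"spacing similar by construction: "
        f"{mu.mean_spacing_um:.2f} vs {wt.mean_spacing_um:.2f} µm"
    )


if __name__ == "__main__":
    main()
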