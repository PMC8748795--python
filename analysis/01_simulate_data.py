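#!/usr/bin/env python
"""Generate the synthetic study datasets with ground truth.

Simulates the three kinds of data the downstream analyses consume:
time-lapse movies of sporulating hyphae for the wild-type-like and
mutant-like imaging phenotypes, septal-labelled vegetative snapshots at
three cross-wall frequency regimes, and replicate spore-volume samples.
Simulated datasets (images, dense ground-truth records, midlines) are
bulky and go under scratch/simulated/; the downstream drivers write their
compact analysis tables to results/.

Run from the repository root:  python analysis/01_simulate_data.py
"""

import os

import septaquant as sq

SCRATCH = "scratch/simulated"
MOVIE_SEEDS = {"wt_like": range(1, 6), "mutant_like": range(101, 106)}
FIELD_SEEDS = {"wt_like": (1000, 1001, 1002), "double_septa": (2000, 2001, 2002),
               "no_septa": (3000, 3001, 3002)}


def main() -> None:
    os.makedirs(SCRATCH, exist_ok=True)

    for name, seeds in MOVIE_SEEDS.items():
        for seed in seeds:
            cfg = sq.preset(name, seed=seed)
            stack, truth = sq.simulate_movie(cfg)
            tag = f"{name}_s{seed}"
            sq.write_stack(stack, os.path.join(SCRATCH, f"movie_{tag}.tif"))
            truth.to_json(os.path.join(SCRATCH, f"truth_{tag}.json"))
            sq.save_config(cfg, os.path.join(SCRATCH, f"config_{tag}.yaml"))
        print(f"{name}: {len(list(seeds))} movies, "
              f"{len(truth.rings)} rings in the last one")

    for name, seeds in FIELD_SEEDS.items():
        for rep, seed in enumerate(seeds):
            cfg = sq.preset(name, seed=seed)
            raster, midlines, truth = sq.simulate_crosswall_field(cfg, n_hyphae=20)
            tag = f"{name}_rep{rep}"
            sq.write_stack(
                sq.TimeLapseStack(raster.values[None], cfg.frame_interval,
                                  cfg.pixel_size),
                os.path.join(SCRATCH, f"field_{tag}.tif"),
            )
            sq.write_midlines(midlines, os.path.join(SCRATCH, f"midlines_{tag}.csv"))
            truth.to_json(os.path.join(SCRATCH, f"truth_{tag}.json"))
        print(f"{name}: 3 fields x 20 hyphae, last field holds "
              f"{len(truth.crosswalls)} cross-walls")

    print(f"datasets and ground truth written under {SCRATCH}/")


if __name__ == "__main__":
    main()
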