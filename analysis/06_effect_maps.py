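#!/usr/bin/env python
"""Channel-wise turn vs. no-turn effect sizes, single subject and group.

Per channel, pairs the mean HbR of each intersection's turn window with its
no-turn window, computes the paired t statistic and Cohen's d (positive d =
stronger HbR decrease while deciding to turn), and checks how well the
top-|d| channels recover the ground-truth activated set. A small cohort is
then averaged channel-wise to show the group-level attenuation of effect
sizes.
"""

import argparse
from pathlib import Path

import numpy as np

from turnintent import io as tio
from turnintent.pipeline import run_cohort, run_subject

OUT = Path("results/analysis/effectmap")


def main(seed: int = 1, subjects: int = 6) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = run_subject(seed=seed, variants=())
    em = res.effect_map
    tio.write_effectmap_csv(em, OUT / "subject_effect_map.csv")
    active = set(res.active_channels.tolist())
    order = em.channel_indices[np.argsort(-np.abs(np.nan_to_num(em.d)))]
    recall = len(set(order[:len(active)].tolist()) & active) / len(active)
    print(f"single subject: d in [{np.nanmin(em.d):.2f}, "
          f"{np.nanmax(em.d):.2f}], top-{len(active)} |d| recall of "
          f"injected channels = {recall:.2f}")

    cohort = run_cohort(subjects, master_seed=seed, variants=())
    g = cohort.group_effect_map
    tio.write_effectmap_csv(g, OUT / "group_effect_map.csv")
    print(f"group of {subjects}: d in [{np.nanmin(g.d):.2f}, "
          f"{np.nanmax(g.d):.2f}] (attenuated by averaging)")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=6)
    main(**vars(ap.parse_args()))
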