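#!/usr/bin/env python
"""Convert the raw recording to band-limited HbO/HbR concentration changes.

Reads results/analysis/subject/recording.snirf (from 01_simulate_subject.py),
applies automated bad-channel rejection, the modified Beer-Lambert conversion
and the 0.01-0.1 Hz zero-phase band-pass, and writes the concentration series
plus the rejection report.
"""

from pathlib import Path

import numpy as np

from turnintent import io as tio
from turnintent.preprocess import PreprocessConfig, preprocess

SUBJ = Path("results/analysis/subject")


def main() -> None:
    rec = tio.read_snirf(SUBJ / "recording.snirf")
    conc = preprocess(rec, PreprocessConfig())
    tio.write_concentration_csv(conc, SUBJ / "concentration")
    print(f"retained {conc.n_channels}/{rec.n_channels} channels "
          f"({len(conc.rejected_channels)} rejected)")
    print(f"HbR fluctuation scale: {np.median(conc.hbr.std(axis=1)):.2e} mmol/l "
          f"(median across channels)")


if __name__ == "__main__":
    main()
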