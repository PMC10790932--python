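#!/usr/bin/env python
"""Event-locked epochs, PCA spectrum and the three feature matrices.

Cuts the turn ([press-2 s, press+2 s)) and no-turn (4 s ending 0.5 s
earlier) windows, fits the channel-space PCA with the 0.7 eigenvalue cutoff
and first-component drop, and reports the instance bookkeeping for the
context / fNIRS / combined variants (1,600 instances per subject).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from turnintent import io as tio
from turnintent.features import build_features, extract_epochs, fit_pca
from turnintent.preprocess import PreprocessConfig, preprocess
from turnintent.simdata import EventLog

SUBJ = Path("results/analysis/subject")


def main() -> None:
    log = EventLog.from_csv(SUBJ / "events.csv")
    rec = tio.read_snirf(SUBJ / "recording.snirf")
    conc = preprocess(rec, PreprocessConfig())
    epochs = extract_epochs(conc, log)
    pca = fit_pca(epochs)
    n_ret = int(np.sum(pca.eigenvalues >= 0.7))
    print(f"{len(epochs)} epochs ({int((epochs.labels == 1).sum())} turn), "
          f"{epochs.samples_per_window} samples per 4-s window")
    print(f"PCA: {n_ret} components pass the 0.7 eigenvalue cutoff; "
          f"first PC (eigenvalue {pca.eigenvalues[0]:.1f}) dropped; "
          f"classifier uses components 2-8")
    rows = []
    for variant in ("context", "fnirs", "combined"):
        fm = build_features(epochs, pca, variant)
        rows.append({"variant": variant, "instances": fm.n_instances,
                     "features": fm.n_features})
        print(f"  {variant:9s}: {fm.n_instances} instances x "
              f"{fm.n_features} features")
    pd.DataFrame(rows).to_csv(SUBJ / "feature_shapes.csv", index=False)
    pd.DataFrame({"component": np.arange(1, 21),
                  "eigenvalue": pca.eigenvalues[:20]}).to_csv(
        SUBJ / "pca_spectrum.csv", index=False)


if __name__ == "__main__":
    main()
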