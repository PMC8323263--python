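#!/usr/bin/env python
"""External validation on the public Bonn EEG benchmark (requires download).

The five-group Bonn benchmark (A/B healthy, C/D interictal, E ictal; 100
single-channel ASCII series of 23.6 s per group) is not redistributed with
this package. To reproduce the two-class experiment (A-D undersampled
against E, full-size architecture, 10-fold cross-validation):

1. Download the five archives (commonly named Z.zip, O.zip, N.zip, F.zip,
   S.zip) from the public mirror of the Bonn epilepsy dataset and unzip
   them into one directory per group.
2. Rename/arrange the files so each group's records live in files named
   ``<class>_<id>.txt`` in a single directory, with classes: Z,O -> normal;
   N,F -> interictal; S -> ictal. One sample value per line (the files
   already use this layout).
3. Run:

    python scripts/bonn_external.py --data-dir /path/to/bonn --out bonn.json

This is a validation aid, not part of the automated checks: it needs the
external download and a full-size training run (hours on CPU).
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from eegrcnn.io import DEFAULT_BONN_FS
from eegrcnn.model import TrainConfig, cross_validate
from eegrcnn.nn.network import ArchitectureSpec
from eegrcnn.tasks import load_bonn_task


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--epochs", type=int, default=512)
    parser.add_argument("--out", type=Path, default=Path("bonn_two_class.json"))
    args = parser.parse_args()

    X, y, groups = load_bonn_task(
        args.data_dir, "two_class", fs=DEFAULT_BONN_FS, window_s=None,
        seed=args.seed,
    )
    cv = cross_validate(
        X, y,
        arch=ArchitectureSpec(n_class=2),
        config=TrainConfig(epochs=args.epochs, batch_size=64, seed=args.seed),
        k=10, seed=args.seed, groups=groups,
    )
    print(cv.summary())
    args.out.write_text(json.dumps(cv.to_manifest(), indent=2) + "\n")


if __name__ == "__main__":
    main()
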