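"""Loading generated cohorts from disk through the real pipeline.

Reads a cohort directory written by :func:`tetcad.synth.write_cohort`
(per-patient page PNGs + ``truth.json`` sidecars, cohort ``metadata.csv``)
and runs every report through preprocessing and lead assembly, using the
sidecar text extractor in place of an OCR engine.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import STATES
from .leads import LeadLayout, assemble_tensor, split_leads
from .nn.network import CLASS_NAMES
from .preprocess import (PreprocessConfig, SidecarTextExtractor,
                         preprocess_report)
from . import defaults

__all__ = ["load_cohort_dataset"]


def load_cohort_dataset(
    cohort_dir: str | Path,
    input_size: int = defaults.INPUT_SIZE,
    config: PreprocessConfig | None = None,
    layout: LeadLayout = LeadLayout(),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load (tensors, integer labels, metadata) from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    metadata = pd.read_csv(cohort_dir / "metadata.csv")
    tensors = np.empty((len(metadata), input_size, input_size, 36), dtype=np.float32)
    labels = np.empty(len(metadata), dtype=np.int64)
    for i, row in metadata.iterrows():
        pdir = cohort_dir / str(row["id"])
        extractor = SidecarTextExtractor.from_patient_dir(pdir)
        pages = preprocess_report(pdir, extractor, config)
        patches = {
            page.state: split_leads(page.pixels, layout)
            for page in pages
            if page.state in STATES
        }
        tensors[i] = assemble_tensor(patches, target_size=input_size).values
        labels[i] = CLASS_NAMES.index(row["label"])
    return tensors, labels, metadata
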