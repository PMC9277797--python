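"""Binning quality metrics against ground-truth labels.

The binning is summarised as a K x S matrix a, where a[k, s] counts reads
placed in bin k whose true species is s. From it:

    precision = sum_k max_s a[k, s] / sum a
    recall    = sum_s max_k a[k, s] / sum a
    F1        = 2 * precision * recall / (precision + recall)

and, per bin (with s* the bin's majority species): completeness
TP / (TP + FN) and contamination 1 - TP / (TP + FP), where TP = a[b, s*],
FP is the rest of the bin and FN the rest of the species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    a: np.ndarray  # K x S integer counts
    bin_labels: list
    species_labels: list
    n_excluded: int = 0  # reads in the binning but absent from truth

    @property
    def total(self) -> int:
        return int(self.a.sum())


def build_confusion(assignment, truth: Mapping[str, str]) -> ConfusionMatrix:
    """Cross-tabulate bin assignments against true species.

    Reads missing from the truth table are excluded (and counted); an empty
    intersection is an error.
    """
    mapping = assignment.mapping if hasattr(assignment, "mapping") else dict(assignment)
    rows = [(b, truth[r]) for r, b in mapping.items() if r in truth]
    n_excluded = len(mapping) - len(rows)
    if n_excluded:
        logger.warning("%d binned reads missing from the truth table were excluded", n_excluded)
    if not rows:
        raise ValueError("no binned read has a ground-truth label")
    df = pd.DataFrame(rows, columns=["bin", "species"])
    tab = pd.crosstab(df["bin"], df["species"])
    return ConfusionMatrix(
        a=tab.to_numpy(dtype=np.int64),
        bin_labels=list(tab.index),
        species_labels=list(tab.columns),
        n_excluded=n_excluded,
    )


def precision_recall_f1(cm: ConfusionMatrix) -> tuple[float, float, float]:
    a = cm.a
    total = a.sum()
    precision = a.max(axis=1).sum() / total
    recall = a.max(axis=0).sum() / total
    f1 = 0.0 if precision + recall == 0 else 2.0 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


def completeness_contamination(cm: ConfusionMatrix) -> dict:
    """Per-bin (completeness, contamination) keyed by bin label.

    The bin's reference species is its majority species.
    """
    a = cm.a
    out = {}
    for b in range(a.shape[0]):
        s_star = int(np.argmax(a[b]))
        tp = int(a[b, s_star])
        fp = int(a[b].sum() - tp)
        fn = int(a[:, s_star].sum() - tp)
        completeness = tp / (tp + fn)
        contamination = 1.0 - tp / (tp + fp)
        out[cm.bin_labels[b]] = (completeness, contamination)
    return out
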