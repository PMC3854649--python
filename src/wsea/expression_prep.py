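"""Expression preprocessing for a binary sample design.

The pipeline mirrors common microarray practice: quantile-normalize the
linear-scale intensity matrix, then compute a per-gene fold change
(mean case / mean control) and a two-tailed pooled-variance Student's
t-test p-value, thresholded at a significance level ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleDesign",
    "quantile_normalize",
    "gene_stats",
    "read_expression_tsv",
    "read_design_tsv",
]


@dataclass(frozen=True)
class SampleDesign:
    """A binary case/control labelling of the sample columns."""

    case: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.case or not self.control:
            raise ValueError("both classes must be non-empty")
        overlap = set(self.case) & set(self.control)
        if overlap:
            raise ValueError(f"samples in both classes: {sorted(overlap)}")

    @classmethod
    def from_mapping(cls, class_of: Mapping[str, str]) -> "SampleDesign":
        """Build from sample → class-label mapping with exactly two labels.

        The label ``case`` (or, failing that, the lexicographically later
        label) is treated as the case class.
        """
        labels = sorted(set(class_of.values()))
        if len(labels) != 2:
            raise ValueError(f"expected exactly two class labels, got {labels}")
        if "case" in labels:
            case_label = "case"
        else:
            case_label = labels[1]
        case = tuple(s for s, c in class_of.items() if c == case_label)
        control = tuple(s for s, c in class_of.items() if c != case_label)
        return cls(case=case, control=control)

    @property
    def samples(self) -> tuple[str, ...]:
        return self.case + self.control

    def validate_against(self, columns: Sequence[str]) -> None:
        missing = set(self.samples) - set(columns)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    The reference distribution is the vector of row means of the
    column-sorted matrix.  Each column's values are replaced by the
    reference value at their rank; tied values within a column receive
    the mean of the reference values their ranks span.

    Idempotent: normalizing an already-normalized matrix is a no-op
    (exactly so for tie-free columns).
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_rows)
        assigned[order] = reference
        # ties: every occurrence of a value gets the mean of the reference
        # entries that the tie group occupies
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        if len(boundaries) < n_rows - 1:  # at least one tie group
            group_of_sorted = np.zeros(n_rows, dtype=int)
            group_of_sorted[boundaries] = 1
            group_of_sorted = np.cumsum(group_of_sorted)
            sums = np.bincount(group_of_sorted, weights=reference)
            counts = np.bincount(group_of_sorted)
            means = sums / counts
            assigned[order] = means[group_of_sorted]
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def gene_stats(
    matrix: pd.DataFrame, design: SampleDesign, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-gene fold change and two-tailed Student's t-test p-value.

    Fold change is mean(case)/mean(control) on the linear intensity
    scale; the t-test uses pooled variance (classical Student's t).  A
    gene whose two groups are identical constants gets t = 0, p = 1.

    Parameters
    ----------
    matrix
        Normalized linear-scale intensities, rows = genes, columns = samples.
    design
        Case/control labelling; each class needs >= 2 samples.
    alpha
        Significance threshold for the ``is_significant`` call.

    Returns
    -------
    DataFrame indexed like ``matrix`` with columns ``fold_change``,
    ``p_value`` and ``is_significant``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    design.validate_against(matrix.columns)
    if len(design.case) < 2 or len(design.control) < 2:
        raise ValueError("each class needs at least 2 samples for the t-test")
    case = matrix.loc[:, list(design.case)].to_numpy(dtype=float)
    ctrl = matrix.loc[:, list(design.control)].to_numpy(dtype=float)

    ctrl_mean = ctrl.mean(axis=1)
    case_mean = case.mean(axis=1)
    zero_ctrl = ctrl_mean == 0
    if np.any(zero_ctrl):
        bad = matrix.index[zero_ctrl].tolist()[:5]
        raise ValueError(
            f"fold change undefined: zero control mean for genes {bad}"
        )
    fold_change = case_mean / ctrl_mean

    res = sps.ttest_ind(case, ctrl, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: scipy yields nan; equal means is the null
    # exactly satisfied (p = 1), unequal means is a sure difference (p = 0)
    nan_mask = np.isnan(p)
    if np.any(nan_mask):
        p[nan_mask] = np.where(case_mean[nan_mask] == ctrl_mean[nan_mask], 1.0, 0.0)

    return pd.DataFrame(
        {
            "fold_change": fold_change,
            "p_value": p,
            "is_significant": p < alpha,
        },
        index=matrix.index,
    )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV: header of sample names, first column row IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    return df


def read_design_tsv(path: str | Path) -> SampleDesign:
    """Read a 2-column headerless design TSV (sample TAB class)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return SampleDesign.from_mapping(dict(zip(df["sample"], df["label"])))
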