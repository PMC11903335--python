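"""The superposition-vector matrix (supQT) and its column filter/normalization.

Every chain-to-chain alignment between complexes Q and T contributes one row:
the 12 numbers (9 rotation entries row-major, 3 translation components in Å)
of its superposition. Columns that barely vary across rows carry no signal for
telling superpositions apart and are excluded by a coefficient-of-variation
criterion; the retained columns are z-scored so rotations (order 1) and
translations (tens of Å) weigh comparably in Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chain_align import ChainAlignment

__all__ = [
    "SuperpositionMatrix",
    "build_matrix",
    "filter_columns",
    "normalize_columns",
    "prepare_matrix",
]

CV_THRESHOLD = 0.1


@dataclass
class SuperpositionMatrix:
    """Rows of superposition vectors plus filtering/normalization state.

    ``retained_mask``, ``column_means``, ``column_sds`` and ``normalized`` are
    populated by :func:`filter_columns` / :func:`normalize_columns`. The s.d.
    is the population s.d. (denominator n) so a two-row column behaves
    deterministically; means enter the CV as absolute values since rotation
    and translation entries are signed.
    """

    rows: np.ndarray
    alignment_refs: list[ChainAlignment]
    retained_mask: np.ndarray | None = None
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float).reshape(-1, 12)
        if len(self.rows) != len(self.alignment_refs):
            raise ValueError("row count must match alignment count")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def build_matrix(alignments: list[ChainAlignment]) -> SuperpositionMatrix:
    """Stack the 12-component superposition vectors of all chain alignments."""
    if not alignments:
        raise ValueError("cannot build a superposition matrix from zero alignments")
    rows = np.stack([a.transform.as_vector12() for a in alignments])
    return SuperpositionMatrix(rows=rows, alignment_refs=list(alignments))


def filter_columns(
    m: SuperpositionMatrix,
    cv_threshold: float = CV_THRESHOLD,
    use_abs_mean: bool = True,
    ddof: int = 0,
) -> SuperpositionMatrix:
    """Mark less-informative columns for exclusion.

    Per column with mean m̄ and s.d. s over rows, the criterion is the
    coefficient of variation s/|m̄|, except that columns whose |mean| is below 1
    are judged on the s.d. directly (a CV denominator near zero would blow up).
    A column is excluded iff its criterion value is below ``cv_threshold``.
    """
    means = m.rows.mean(axis=0)
    sds = m.rows.std(axis=0, ddof=ddof)
    denom = np.abs(means) if use_abs_mean else means
    with np.errstate(divide="ignore", invalid="ignore"):
        criterion = np.where(np.abs(denom) >= 1.0, sds / np.abs(denom), sds)
    retained = criterion >= cv_threshold
    return replace(m, retained_mask=retained, column_means=means, column_sds=sds)


def normalize_columns(m: SuperpositionMatrix) -> SuperpositionMatrix:
    """Z-score the retained columns.

    If every column was excluded (all superpositions effectively identical) the
    normalized matrix has zero columns: all rows sit at mutual distance 0 and
    clustering degenerates to a single cluster, which is the physically correct
    reading of "nothing distinguishes the superpositions".
    """
    if m.retained_mask is None:
        raise ValueError("filter_columns must run before normalize_columns")
    cols = np.flatnonzero(m.retained_mask)
    centered = m.rows[:, cols] - m.column_means[cols]
    sds = m.column_sds[cols]
    safe = np.where(sds > 0, sds, 1.0)  # sd==0 retained columns: center only
    return replace(m, normalized=centered / safe)


def prepare_matrix(alignments: list[ChainAlignment], **filter_kwargs) -> SuperpositionMatrix:
    """Convenience: build, filter and normalize in one call."""
    return normalize_columns(filter_columns(build_matrix(alignments), **filter_kwargs))
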