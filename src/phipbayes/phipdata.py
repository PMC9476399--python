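"""Data model and I/O for PhIP-Seq peptide read-count matrices.

A PhIP-Seq plate yields an integer matrix of read counts, peptides by
samples.  Samples are either mock immunoprecipitations without antibody
input ("beads-only"), which define the per-peptide background binding
distribution, or serum samples in which antibody-reactive peptides pull
more reads than that background predicts.  All downstream estimators
consume the :class:`PeptideCountMatrix` defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEADS = "beads"
SERUM = "serum"
_ROLES = frozenset({BEADS, SERUM})


class PhipDataError(ValueError):
    """Malformed or inconsistent count/annotation input."""


@dataclass
class PeptideCountMatrix:
    """Read counts for one plate with per-sample roles and library sizes.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, peptides (rows, indexed by peptide id)
        by samples (columns, sample ids).
    roles : pandas.Series
        Per-sample label, ``"beads"`` for mock IPs or ``"serum"``,
        indexed by sample id.
    library_sizes : pandas.Series, optional
        Total read count :math:`n_j` per sample.  Computed as column sums
        when omitted; if given they must equal the column sums.
    """

    counts: pd.DataFrame
    roles: pd.Series
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise PhipDataError("duplicate peptide ids")
        if c.columns.has_duplicates:
            raise PhipDataError("duplicate sample ids")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise PhipDataError("counts must be integers")
            self.counts = c = c.round().astype(np.int64)
            vals = c.to_numpy()
        if (vals < 0).any():
            raise PhipDataError("counts must be non-negative")

        missing = c.columns.difference(self.roles.index)
        if len(missing):
            raise PhipDataError(
                f"samples missing from annotation: {list(missing)}"
            )
        self.roles = self.roles.reindex(c.columns)
        bad = set(self.roles.unique()) - _ROLES
        if bad:
            raise PhipDataError(f"unknown sample roles: {sorted(bad)}")

        self.counts.index.name = "peptide_id"
        self.counts.columns.name = None
        self.roles.index.name = None
        self.roles.name = None

        colsums = c.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = colsums
        else:
            self.library_sizes = self.library_sizes.reindex(c.columns)
            if not np.array_equal(
                self.library_sizes.to_numpy(), colsums.to_numpy()
            ):
                raise PhipDataError("library sizes must equal column sums")
        if (self.library_sizes <= 0).any():
            raise PhipDataError("every sample needs at least one read")

    # ------------------------------------------------------------------
    @property
    def peptide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def beads_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == BEADS])

    @property
    def serum_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == SERUM])

    @property
    def n_peptides(self) -> int:
        return self.counts.shape[0]

    def beads_counts(self) -> pd.DataFrame:
        return self.counts[self.beads_ids]

    def drop_peptides(self, peptide_ids) -> "PeptideCountMatrix":
        """Remove peptides and recompute library sizes from the remainder."""
        drop = set(peptide_ids)
        sub = self.counts.loc[[p for p in self.counts.index if p not in drop]]
        return PeptideCountMatrix(sub.copy(), self.roles.copy())

    def with_role(self, sample_id: str, role: str) -> "PeptideCountMatrix":
        roles = self.roles.copy()
        roles.loc[sample_id] = role
        return PeptideCountMatrix(self.counts.copy(), roles)

    # ------------------------------------------------------------------
    def to_tsv(self, counts_path, annotation_path) -> None:
        out = self.counts.copy()
        out.index.name = "peptide_id"
        out.to_csv(counts_path, sep="\t")
        ann = pd.DataFrame(
            {"sample_id": self.roles.index, "role": self.roles.to_numpy()}
        )
        ann.to_csv(annotation_path, sep="\t", index=False)


def read_counts(counts_path, annotation_path) -> PeptideCountMatrix:
    """Load a count matrix and its sample annotation from TSV files.

    The counts file has a header row of sample ids and a first column
    ``peptide_id``; the annotation file has columns ``sample_id`` and
    ``role`` (``beads`` or ``serum``).  Library sizes are computed as
    column sums.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    if not {"sample_id", "role"} <= set(ann.columns):
        raise PhipDataError("annotation needs 'sample_id' and 'role' columns")
    roles = ann.set_index("sample_id")["role"]
    if roles.index.has_duplicates:
        raise PhipDataError("duplicate sample ids in annotation")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    roles.index = roles.index.astype(str)
    return PeptideCountMatrix(counts, roles)


def leave_one_beads_out(
    m: PeptideCountMatrix, held_out: str
) -> PeptideCountMatrix:
    """Relabel one beads-only sample as serum for a round-robin run.

    Running each mock IP against the remaining beads-only samples measures
    the false-positive behaviour of a detection method: the held-out column
    is drawn from the same background as the rest, so every enrichment call
    on it is false.
    """
    if held_out not in m.sample_ids:
        raise KeyError(held_out)
    if m.roles.loc[held_out] != BEADS:
        raise ValueError(f"{held_out!r} is not a beads-only sample")
    return m.with_role(held_out, SERUM)
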