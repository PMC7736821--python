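"""Per-bond cleavage profiles from alignments or count tables.

A :class:`CleavageProfile` records, for one reference in one sample, how many
retained fragment boundaries fall on each internucleotide bond. Bond *b*
(1-based, b = 1..L-1) lies between nucleotides *b* and *b+1*; a fragment
spanning nucleotides s..t contributes one event at bond s-1 (its 5' boundary,
if s > 1) and one at bond t (its 3' boundary, if t < L). Molecule termini
(bonds 0 and L) are never counted: a fragment end at the molecule terminus is
not a hydrolysis product.

Both ends contribute by default (combined 5'+3' counting, doubling effective
depth); ``ends="five"``/``"three"`` restricts to one side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .refmodel import RnaRef

logger = logging.getLogger(__name__)


class ProfileError(ValueError):
    pass


@dataclass
class CleavageProfile:
    """Per-bond fragment-boundary counts for one reference in one sample."""

    ref_id: str
    counts: np.ndarray  # length L-1, counts[b-1] is bond b
    n_fragments: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ProfileError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ProfileError("counts must be non-negative")
        if self.counts.sum() > 2 * self.n_fragments:
            raise ProfileError(
                f"{self.ref_id}: sum(counts)={int(self.counts.sum())} exceeds "
                f"2 * n_fragments={2 * self.n_fragments}"
            )

    @property
    def n_bonds(self) -> int:
        return len(self.counts)

    def bond(self, b: int) -> int:
        """Count at 1-based bond b."""
        if not 1 <= b <= self.n_bonds:
            raise ProfileError(f"bond {b} outside 1..{self.n_bonds}")
        return int(self.counts[b - 1])

    def __add__(self, other: "CleavageProfile") -> "CleavageProfile":
        if other.ref_id != self.ref_id or other.n_bonds != self.n_bonds:
            raise ProfileError("profiles must share ref_id and length to add")
        return CleavageProfile(
            self.ref_id,
            self.counts + other.counts,
            self.n_fragments + other.n_fragments,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CleavageProfile):
            return NotImplemented
        return (
            self.ref_id == other.ref_id
            and self.n_fragments == other.n_fragments
            and np.array_equal(self.counts, other.counts)
        )


def profile_from_fragments(
    fragments: np.ndarray, ref: RnaRef, ends: str = "both"
) -> CleavageProfile:
    """Count fragment boundaries directly from an (N, 2) start/end array."""
    L = ref.length
    frags = np.asarray(fragments, dtype=np.int64).reshape(-1, 2)
    counts = np.zeros(L - 1, dtype=np.int64)
    if len(frags):
        starts, ends_ = frags[:, 0], frags[:, 1]
        if (starts < 1).any() or (ends_ > L).any() or (starts > ends_).any():
            raise ProfileError(f"{ref.ref_id}: fragment outside 1..{L}")
        if ends in ("both", "five"):
            b5 = starts[starts > 1] - 1
            counts += np.bincount(b5 - 1, minlength=L - 1)
        if ends in ("both", "three"):
            b3 = ends_[ends_ < L]
            counts += np.bincount(b3 - 1, minlength=L - 1)
        if ends not in ("both", "five", "three"):
            raise ProfileError(f"unknown ends mode {ends!r}")
    return CleavageProfile(ref.ref_id, counts, n_fragments=len(frags))


def profile_from_alignments(
    sam_path, refs: Mapping[str, RnaRef], ends: str = "both",
    allow_clipped: bool = False,
) -> dict[str, CleavageProfile]:
    """Build per-reference profiles from a single-end SAM file.

    Only mapped primary alignments are used; secondary and supplementary
    records are skipped (count logged). Soft/hard-clipped alignments are
    rejected by default because clipping changes the inferred cleavage
    position; ``allow_clipped=True`` uses the aligned span instead.
    """
    frags: dict[str, list[tuple[int, int]]] = {rid: [] for rid in refs}
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            rid = rec.reference_name
            if rid not in refs:
                raise ProfileError(f"alignment references unknown ref {rid!r}")
            if not allow_clipped and any(
                op in (4, 5) for op, _ in (rec.cigartuples or [])
            ):
                n_skipped += 1
                continue
            s = rec.reference_start + 1  # 1-based first nucleotide
            t = rec.reference_end  # 1-based last nucleotide (pysam end is excl.)
            frags[rid].append((s, t))
    if n_skipped:
        logger.info("skipped %d secondary/supplementary/clipped records", n_skipped)
    return {
        rid: profile_from_fragments(
            np.array(fl, dtype=np.int64).reshape(-1, 2), refs[rid], ends=ends
        )
        for rid, fl in frags.items()
    }


def profile_from_counts(tsv_path, refs: Mapping[str, RnaRef]) -> dict[str, CleavageProfile]:
    """Load per-bond count tables (TSV ``ref_id  bond  count``).

    Missing bonds default to 0. ``n_fragments`` is reconstructed as
    ceil(sum/2) (each fragment contributes at most two boundary events).
    """
    tab = pd.read_csv(tsv_path, sep="\t")
    profiles = {
        rid: np.zeros(ref.length - 1, dtype=np.int64) for rid, ref in refs.items()
    }
    if not tab.empty:
        for _, row in tab.iterrows():
            rid = row["ref_id"]
            if rid not in refs:
                raise ProfileError(f"count table names unknown ref {rid!r}")
            b, c = int(row["bond"]), int(row["count"])
            L = refs[rid].length
            if not 1 <= b <= L - 1:
                raise ProfileError(f"{rid}: bond {b} outside 1..{L - 1}")
            profiles[rid][b - 1] = c
    return {
        rid: CleavageProfile(rid, counts, n_fragments=math.ceil(counts.sum() / 2))
        for rid, counts in profiles.items()
    }


def write_counts(profiles: Mapping[str, CleavageProfile], tsv_path) -> None:
    """Export profiles as TSV ``ref_id  bond  count`` (nonzero bonds only)."""
    rows = []
    for rid, prof in profiles.items():
        for b in np.flatnonzero(prof.counts):
            rows.append((rid, int(b) + 1, int(prof.counts[b])))
    pd.DataFrame(rows, columns=["ref_id", "bond", "count"]).to_csv(
        tsv_path, sep="\t", index=False
    )
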