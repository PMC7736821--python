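"""Reference sequences and the 2'-O-methylation (Nm) site model.

Every downstream stage — the hydrolysis simulator, fragment-end counting,
MethScore — indexes against the objects defined here: :class:`RnaRef`, one
mature reference molecule (tRNA or rRNA) with a pool abundance weight, and
:class:`NmSite`, one candidate 2'-O-methylated position.

Coordinates are 1-based along the mature sequence (CCA included for tRNAs).
Canonical tRNA numbering such as "18" or "32" is carried as a display label
(``pos_label``) and is never used for indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

_RNA_ALPHABET = set("ACGU")

TRNA = "tRNA"
RRNA = "rRNA"

# site classes
GM18 = "Gm18"
NM32 = "Nm32"
NM34 = "Nm34"
RRNA_NM = "rRNA"


class RefModelError(ValueError):
    """Raised when references or site tables violate the model invariants."""


@dataclass(frozen=True)
class RnaRef:
    """One reference RNA molecule.

    Parameters
    ----------
    ref_id : str
        Unique identifier (FASTA record id).
    sequence : str
        Uppercase RNA sequence (A/C/G/U only).
    abundance : float
        Non-negative pool weight in arbitrary molar units. Low-abundance
        references receive proportionally fewer simulated molecules, which
        reproduces the insufficient-coverage exclusion pathway seen for rare
        isoacceptors.
    molecule_class : str
        ``"tRNA"`` or ``"rRNA"``.
    """

    ref_id: str
    sequence: str
    abundance: float = 1.0
    molecule_class: str = TRNA

    def __post_init__(self) -> None:
        if not self.ref_id:
            raise RefModelError("ref_id must be non-empty")
        if not self.sequence:
            raise RefModelError(f"{self.ref_id}: sequence must be non-empty")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise RefModelError(
                f"{self.ref_id}: sequence contains non-RNA characters {sorted(bad)}"
            )
        if self.abundance < 0:
            raise RefModelError(f"{self.ref_id}: abundance must be >= 0")
        if self.molecule_class not in (TRNA, RRNA):
            raise RefModelError(
                f"{self.ref_id}: molecule_class must be {TRNA!r} or {RRNA!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NmSite:
    """One candidate 2'-O-methylated position on a reference.

    ``position`` indexes the mature sequence 1-based; ``base`` must equal the
    nucleotide there. ``site_class`` groups sites the way the analysis reports
    them: D-loop Gm18, anticodon-loop positions 32 and 34, or rRNA.
    ``measurable`` marks sites that survive the coverage-based exclusions.
    ``placeholder`` flags synthetic fixture rows whose isoacceptor identity is
    not biologically curated.
    """

    ref_id: str
    position: int
    pos_label: str
    base: str
    mod_name: str
    site_class: str
    measurable: bool = True
    placeholder: bool = False

    @property
    def key(self) -> tuple[str, int]:
        return (self.ref_id, self.position)


def _validate_site(site: NmSite, ref: RnaRef, row: object = None) -> None:
    ctx = f" (row {row})" if row is not None else ""
    if not 1 <= site.position <= ref.length:
        raise RefModelError(
            f"{site.ref_id}:{site.position}{ctx}: position outside 1..{ref.length}"
        )
    actual = ref.sequence[site.position - 1]
    if site.base != actual:
        raise RefModelError(
            f"{site.ref_id}:{site.position}{ctx}: site table claims base "
            f"{site.base!r} but sequence has {actual!r}"
        )
    if site.site_class not in (GM18, NM32, NM34, RRNA_NM):
        raise RefModelError(f"{site.ref_id}:{site.position}{ctx}: "
                            f"unknown site_class {site.site_class!r}")


def classify_site(pos_label: str, molecule_class: str) -> str:
    """Derive the site class from the canonical position label."""
    if molecule_class == RRNA:
        return RRNA_NM
    if pos_label == "18":
        return GM18
    if pos_label == "32":
        return NM32
    if pos_label == "34":
        return NM34
    raise RefModelError(
        f"cannot classify tRNA site with pos_label {pos_label!r}; "
        "known labels are 18, 32, 34"
    )


def load_refs(
    fasta_path,
    abundance_table=None,
    molecule_classes: Mapping[str, str] | None = None,
) -> dict[str, RnaRef]:
    """Load reference molecules from FASTA, optionally with abundances.

    DNA-style ``T`` is transliterated to ``U``. Missing abundances default to
    1.0. ``molecule_classes`` maps ref_id to ``"tRNA"``/``"rRNA"``; ids not
    listed default to tRNA.

    Returns an ordered dict ``ref_id -> RnaRef``. Raises
    :class:`RefModelError` on an empty FASTA or a duplicate id.
    """
    abund: dict[str, float] = {}
    if abundance_table is not None:
        tab = pd.read_csv(abundance_table, sep="\t")
        if not {"ref_id", "abundance"} <= set(tab.columns):
            raise RefModelError(
                "abundance table needs columns 'ref_id' and 'abundance'"
            )
        abund = dict(zip(tab["ref_id"], tab["abundance"].astype(float)))

    refs: dict[str, RnaRef] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in refs:
            raise RefModelError(f"duplicate ref_id {rec.id!r} in FASTA")
        seq = str(rec.seq).upper().replace("T", "U")
        mclass = (molecule_classes or {}).get(rec.id, TRNA)
        refs[rec.id] = RnaRef(
            ref_id=rec.id,
            sequence=seq,
            abundance=float(abund.pop(rec.id, 1.0)),
            molecule_class=mclass,
        )
    if not refs:
        raise RefModelError(f"no records in FASTA {fasta_path}")
    if abund:
        raise RefModelError(
            f"abundance table names unknown ref_ids: {sorted(abund)}"
        )
    return refs


_SITE_COLUMNS = ["ref_id", "position", "pos_label", "base", "mod_name", "site_class"]


def load_sites(tsv_path, refs: Mapping[str, RnaRef]) -> list[NmSite]:
    """Load and validate the Nm site table against the references.

    The TSV needs columns ``ref_id position pos_label base mod_name
    site_class`` (optional: ``measurable``, ``placeholder``). An empty
    ``site_class`` cell is derived from ``pos_label`` and the reference's
    molecule class. Every row is checked: the reference must exist, the
    position must be in range, and ``base`` must match the sequence.
    """
    tab = pd.read_csv(tsv_path, sep="\t", dtype={"pos_label": str})
    if tab.empty:
        return []
    missing = set(_SITE_COLUMNS[:5]) - set(tab.columns)
    if missing:
        raise RefModelError(f"site table missing columns {sorted(missing)}")

    sites: list[NmSite] = []
    for idx, row in tab.iterrows():
        ref_id = row["ref_id"]
        if ref_id not in refs:
            raise RefModelError(f"row {idx}: unknown ref_id {ref_id!r}")
        ref = refs[ref_id]
        sc = row.get("site_class")
        if sc is None or (isinstance(sc, float) and pd.isna(sc)) or sc == "":
            sc = classify_site(str(row["pos_label"]), ref.molecule_class)
        site = NmSite(
            ref_id=ref_id,
            position=int(row["position"]),
            pos_label=str(row["pos_label"]),
            base=str(row["base"]),
            mod_name=str(row["mod_name"]),
            site_class=str(sc),
            measurable=bool(row.get("measurable", True)),
            placeholder=bool(row.get("placeholder", False)),
        )
        _validate_site(site, ref, row=idx)
        sites.append(site)
    return sites


def sites_to_frame(sites: Iterable[NmSite]) -> pd.DataFrame:
    """Tabulate sites; the inverse of :func:`load_sites` via ``to_csv``."""
    return pd.DataFrame(
        [
            {
                "ref_id": s.ref_id,
                "position": s.position,
                "pos_label": s.pos_label,
                "base": s.base,
                "mod_name": s.mod_name,
                "site_class": s.site_class,
                "measurable": s.measurable,
                "placeholder": s.placeholder,
            }
            for s in sites
        ],
        columns=_SITE_COLUMNS + ["measurable", "placeholder"],
    )


def filter_measurable(
    sites: Sequence[NmSite],
    exclusions: Iterable[str] = (),
) -> tuple[list[NmSite], dict[str, int]]:
    """Drop excluded references' sites; return kept sites and a class summary.

    ``exclusions`` is a collection of ref_ids whose sites are removed from
    the measurable set (the insufficient-coverage exclusion applied to rare
    isoacceptors). An exclusion matching no site raises a warning, not an
    error. Kept sites are returned with ``measurable=True``; the summary
    counts kept sites per site class.
    """
    excl = set(exclusions)
    matched = {s.ref_id for s in sites} & excl
    for missing in sorted(excl - matched):
        warnings.warn(f"exclusion {missing!r} matches no site", stacklevel=2)

    kept = [
        NmSite(
            ref_id=s.ref_id,
            position=s.position,
            pos_label=s.pos_label,
            base=s.base,
            mod_name=s.mod_name,
            site_class=s.site_class,
            measurable=True,
            placeholder=s.placeholder,
        )
        for s in sites
        if s.ref_id not in excl
    ]
    summary = {cls: 0 for cls in (GM18, NM32, NM34, RRNA_NM)}
    for s in kept:
        summary[s.site_class] += 1
    return kept, summary
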