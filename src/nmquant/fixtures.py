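"""Packaged reference fixture: the E. coli Nm site model at desk scale.

The fixture enumerates the 20 candidate tRNA 2'-O-methylation sites of the
E. coli model — 12 D-loop Gm18 sites, 6 anticodon-loop sites at position 32
and 2 at the wobble position 34 — plus the four known rRNA Nm sites
(16S m4Cm1402, 23S Cm2498/Gm2251/Um2552) on short synthetic rRNA stubs.

Only part of the isoacceptor identities are curated (the named responsive
tRNAs, the rare isoacceptors excluded for insufficient coverage, and the
named anticodon-loop carriers); the remaining rows are synthetic placeholder
isoacceptors flagged ``placeholder=True``. Class cardinalities, not
placeholder identities, are the modelled quantity. Sequences are synthetic:
deterministic pseudo-random RNA with the expected base planted at each site
position and a CCA 3' end for tRNAs; rRNA site residue numbers (e.g. 2552)
are display labels on placeholder stub coordinates.

Rare isoacceptors carry a low abundance weight so that the simulator's
coverage gate reproduces their exclusion pathway.
"""

from __future__ import annotations

import zlib

import numpy as np

from .refmodel import (
    GM18,
    NM32,
    NM34,
    RRNA,
    RRNA_NM,
    TRNA,
    NmSite,
    RnaRef,
    sites_to_frame,
)

#: rare isoacceptors whose Gm18 sites are excluded (insufficient D-loop coverage)
RARE_ISOACCEPTORS = (
    "tRNA-Ile-k2CAU",
    "tRNA-Met-ac4CAU",
    "tRNA-Gln-UsUG",
)

#: the five stress-responsive Gm18 carriers used in perturbation scenarios
RESPONSIVE_GM18 = (
    "tRNA-Leu-cmnm5UmAA",
    "tRNA-Ser-CGA",
    "tRNA-Pro-GGG",
    "tRNA-Arg-ICG",
    "tRNA-Gly-GCC",
)

_TRNA_LEN = 76

# (ref_id, abundance, placeholder) for the 12 Gm18 carriers
_GM18_CARRIERS = [
    ("tRNA-Leu-cmnm5UmAA", 1.0, False),
    ("tRNA-Ser-CGA", 1.2, False),
    ("tRNA-Pro-GGG", 0.8, True),
    ("tRNA-Arg-ICG", 1.5, True),
    ("tRNA-Gly-GCC", 2.0, True),
    ("tRNA-Thr-GGU", 0.9, True),
    ("tRNA-Val-UAC", 1.1, True),
    ("tRNA-Ala-UGC", 1.4, True),
    ("tRNA-His-GUG", 0.7, True),
    ("tRNA-Ile-k2CAU", 0.02, False),
    ("tRNA-Met-ac4CAU", 0.02, False),
    ("tRNA-Gln-UsUG", 0.02, False),
]

# (ref_id, abundance, base at 32, mod_name, placeholder)
_NM32_CARRIERS = [
    ("tRNA-Ser-cmo5UGA", 1.0, "C", "Cm32", False),
    ("tRNA-Phe-GAA", 1.3, "C", "Cm32", True),
    ("tRNA-Trp-CCA", 0.9, "C", "Cm32", True),
    ("tRNA-Gln-CUG", 1.1, "U", "Um32", True),
    ("tRNA-Glu-UUC", 1.6, "U", "Um32", True),
    ("tRNA-Asp-GUC", 1.2, "C", "Cm32", True),
]

# (ref_id, base at 34, mod_name); Leu-cmnm5UmAA also carries Gm18
_NM34_CARRIERS = [
    ("tRNA-Leu-CmAA", "C", "Cm34"),
    ("tRNA-Leu-cmnm5UmAA", "U", "cmnm5Um34"),
]

# (stub_id, length, [(position, pos_label, base, mod_name)])
_RRNA_STUBS = [
    ("rRNA-16S-stub", 150, [(60, "1402", "C", "m4Cm1402")]),
    (
        "rRNA-23S-stub",
        220,
        [
            (70, "2251", "G", "Gm2251"),
            (130, "2498", "C", "Cm2498"),
            (180, "2552", "U", "Um2552"),
        ],
    ),
]

_BASES = np.array(list("ACGU"))


def _synthetic_sequence(ref_id: str, length: int, planted: dict[int, str]) -> str:
    """Deterministic pseudo-random RNA with required bases planted 1-based."""
    rng = np.random.default_rng(zlib.crc32(ref_id.encode()) & 0x7FFFFFFF)
    seq = list(_BASES[rng.integers(0, 4, size=length)])
    for pos, base in planted.items():
        seq[pos - 1] = base
    return "".join(seq)


def gm18_carrier_ids() -> list[str]:
    """ref_ids of the 12 Gm18-carrying tRNAs (rare isoacceptors included)."""
    return [rid for rid, _, _ in _GM18_CARRIERS]


def builtin_refs() -> dict[str, RnaRef]:
    """The fixture's reference pool: 19 tRNAs plus two rRNA stubs."""
    refs: dict[str, RnaRef] = {}

    planted_by_ref: dict[str, dict[int, str]] = {}
    abundance: dict[str, float] = {}
    for ref_id, ab, _ in _GM18_CARRIERS:
        planted_by_ref.setdefault(ref_id, {})[18] = "G"
        abundance[ref_id] = ab
    for ref_id, ab, base, _, _ in _NM32_CARRIERS:
        planted_by_ref.setdefault(ref_id, {})[32] = base
        abundance.setdefault(ref_id, ab)
    for ref_id, base, _ in _NM34_CARRIERS:
        planted_by_ref.setdefault(ref_id, {})[34] = base
        abundance.setdefault(ref_id, 1.0)

    for ref_id, planted in planted_by_ref.items():
        planted = dict(planted)
        # mature tRNA ends in CCA
        planted.update({_TRNA_LEN - 2: "C", _TRNA_LEN - 1: "C", _TRNA_LEN: "A"})
        refs[ref_id] = RnaRef(
            ref_id=ref_id,
            sequence=_synthetic_sequence(ref_id, _TRNA_LEN, planted),
            abundance=abundance[ref_id],
            molecule_class=TRNA,
        )

    for stub_id, length, site_rows in _RRNA_STUBS:
        planted = {pos: base for pos, _, base, _ in site_rows}
        refs[stub_id] = RnaRef(
            ref_id=stub_id,
            sequence=_synthetic_sequence(stub_id, length, planted),
            abundance=5.0,
            molecule_class=RRNA,
        )
    return refs


def builtin_sites() -> list[NmSite]:
    """All 24 candidate sites: 20 tRNA (12 Gm18, 6 Nm32, 2 Nm34) + 4 rRNA."""
    sites: list[NmSite] = []
    for ref_id, _, placeholder in _GM18_CARRIERS:
        sites.append(
            NmSite(ref_id, 18, "18", "G", "Gm18", GM18, placeholder=placeholder)
        )
    for ref_id, _, base, mod, placeholder in _NM32_CARRIERS:
        sites.append(
            NmSite(ref_id, 32, "32", base, mod, NM32, placeholder=placeholder)
        )
    for ref_id, base, mod in _NM34_CARRIERS:
        sites.append(NmSite(ref_id, 34, "34", base, mod, NM34, placeholder=False))
    for stub_id, _, site_rows in _RRNA_STUBS:
        for pos, label, base, mod in site_rows:
            sites.append(
                NmSite(stub_id, pos, label, base, mod, RRNA_NM, placeholder=True)
            )
    return sites


def trna_sites() -> list[NmSite]:
    """The 20 candidate tRNA sites only."""
    return [s for s in builtin_sites() if s.site_class != RRNA_NM]


def write_fixture(outdir) -> dict[str, str]:
    """Write the fixture as FASTA + TSV files; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = builtin_refs()

    fasta = outdir / "references.fasta"
    with open(fasta, "w") as fh:
        for ref in refs.values():
            fh.write(f">{ref.ref_id}\n{ref.sequence}\n")

    abund = outdir / "abundances.tsv"
    with open(abund, "w") as fh:
        fh.write("ref_id\tabundance\n")
        for ref in refs.values():
            fh.write(f"{ref.ref_id}\t{ref.abundance}\n")

    classes = outdir / "molecule_classes.tsv"
    with open(classes, "w") as fh:
        fh.write("ref_id\tmolecule_class\n")
        for ref in refs.values():
            fh.write(f"{ref.ref_id}\t{ref.molecule_class}\n")

    sites = outdir / "sites.tsv"
    sites_to_frame(builtin_sites()).to_csv(sites, sep="\t", index=False)

    return {
        "references": str(fasta),
        "abundances": str(abund),
        "molecule_classes": str(classes),
        "sites": str(sites),
    }
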