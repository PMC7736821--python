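"""Alkaline-hydrolysis fragmentation simulator with Nm protection.

The measurement model behind RiboMethSeq-style Nm mapping: each molecule of a
reference RNA is methylated at each candidate site independently
(Bernoulli(f), with f the site's stoichiometry in that condition); alkaline
hydrolysis then cleaves each internal phosphodiester bond independently with
probability q — except the bond immediately 3' of a 2'-O-methylated ribose,
which is fully protected (cleavage probability 0). Maximal uncleaved runs
become fragments; a size-selection window retains library-like fragment
lengths; retained fragment boundaries are tallied per bond, excluding
molecule termini, yielding the :class:`~nmquant.endcount.CleavageProfile`
that MethScore consumes.

The same ground-truth stoichiometries drive a lognormal-noise model of
global modified-nucleoside content, emulating the orthogonal LC-MS readout.

All randomness flows from explicit seeds; per-sample streams are derived
deterministically from (master seed, sample id), so replicates differ but a
rerun is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .endcount import CleavageProfile, profile_from_fragments
from .refmodel import NmSite, RnaRef


class SimulationError(ValueError):
    pass


class Fragment(NamedTuple):
    """One hydrolysis fragment, 1-based inclusive coordinates."""

    ref_id: str
    start: int
    end: int


@dataclass(frozen=True)
class SimParams:
    """Simulator settings.

    cleavage_prob : per-bond hydrolysis probability q in (0, 1].
    n_molecules : molecules simulated per reference per sample, scaled by
        relative abundance (a ref at half the maximum abundance gets half
        the molecules).
    size_min, size_max : retained fragment length bounds (nt), emulating
        library size selection. The default 10-50 nt window keeps the
        size-selection censoring boundary well away from the D-loop scoring
        window: a lower bound of 20 nt would make 3'-boundary events at bonds
        below 20 impossible while leaving bond 20 unaffected, biasing the
        neighborhood mean at position-18 sites.
    seed : integer RNG seed.
    stoich : map (ref_id, position) -> methylation fraction f in [0, 1].

    Defaults (q = 0.05, 10-50 nt retained, 2e5 molecules) give a mean
    neighbor coverage of several thousand events per bond on a 76-nt tRNA,
    enough for stoichiometry recovery at the 0.05 level in seconds.
    """

    cleavage_prob: float = 0.05
    n_molecules: int = 200_000
    size_min: int = 10
    size_max: int = 50
    seed: int = 0
    stoich: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.cleavage_prob <= 1:
            raise SimulationError("cleavage_prob must be in (0, 1]")
        if self.n_molecules < 0:
            raise SimulationError("n_molecules must be >= 0")
        if not 1 <= self.size_min <= self.size_max:
            raise SimulationError("need 1 <= size_min <= size_max")
        for key, f in self.stoich.items():
            if not 0 <= f <= 1:
                raise SimulationError(f"stoichiometry {f} at {key} outside [0, 1]")


def _sample_seed(master_seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample stream, stable across processes."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(sample_id.encode())])
    )


def simulate_fragments(
    ref: RnaRef,
    sites: Sequence[NmSite],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, CleavageProfile, dict[tuple[str, int], float]]:
    """Simulate one reference in one sample.

    Returns ``(fragments, profile, truth)`` where ``fragments`` is an (N, 2)
    int array of retained (start, end) pairs, ``profile`` counts their
    boundaries per bond, and ``truth`` maps (ref_id, position) to the
    stoichiometry used (defaulting to 0 for sites absent from
    ``params.stoich``).

    Protection is absolute: a molecule methylated at site n can never be
    cleaved at bond n, so with f = 1 the end count at bond n is exactly 0.
    """
    for s in sites:
        if s.ref_id != ref.ref_id:
            raise SimulationError(f"site {s.ref_id}:{s.position} not on {ref.ref_id}")
    L = ref.length
    truth = {
        (ref.ref_id, s.position): float(params.stoich.get((ref.ref_id, s.position), 0.0))
        for s in sites
    }
    n = params.n_molecules
    if n == 0 or L < 2:
        return (
            np.empty((0, 2), dtype=np.int64),
            CleavageProfile(ref.ref_id, np.zeros(max(L - 1, 0), dtype=np.int64), 0),
            truth,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)

    # cleave[m, b-1]: molecule m hydrolysed at bond b
    cleave = rng.random((n, L - 1)) < params.cleavage_prob
    for s in sites:
        f = truth[(ref.ref_id, s.position)]
        if s.position <= L - 1:  # bond 3' of the ribose exists
            methylated = rng.random(n) < f
            cleave[methylated, s.position - 1] = False

    rows, cols = np.nonzero(cleave)  # row-major: sorted per molecule
    bonds = cols + 1  # 1-based cut bonds

    # fragments ending at each cut bond, plus one trailing fragment per molecule
    if len(bonds):
        same_row = np.empty(len(bonds), dtype=bool)
        same_row[0] = False
        same_row[1:] = rows[1:] == rows[:-1]
        prev_bond = np.empty(len(bonds), dtype=np.int64)
        prev_bond[0] = 0
        prev_bond[1:] = bonds[:-1]
        starts_mid = np.where(same_row, prev_bond + 1, 1)
        ends_mid = bonds
        # last cut per molecule -> trailing fragment start
        last_of_row = np.empty(len(bonds), dtype=bool)
        last_of_row[:-1] = rows[1:] != rows[:-1]
        last_of_row[-1] = True
        trail_start = np.full(n, 1, dtype=np.int64)
        trail_start[rows[last_of_row]] = bonds[last_of_row] + 1
    else:
        starts_mid = np.empty(0, dtype=np.int64)
        ends_mid = np.empty(0, dtype=np.int64)
        trail_start = np.full(n, 1, dtype=np.int64)

    starts = np.concatenate([starts_mid, trail_start])
    ends = np.concatenate([ends_mid, np.full(n, L, dtype=np.int64)])

    lengths = ends - starts + 1
    keep = (lengths >= params.size_min) & (lengths <= params.size_max)
    fragments = np.column_stack([starts[keep], ends[keep]])

    profile = profile_from_fragments(fragments, ref)
    return fragments, profile, truth


def fragment_records(fragments: np.ndarray, ref: RnaRef) -> list[Fragment]:
    """View an (N, 2) fragment array as Fragment tuples (small N only)."""
    return [Fragment(ref.ref_id, int(s), int(e)) for s, e in np.asarray(fragments)]


def emit_sam(fragments, ref: RnaRef, sam_path) -> None:
    """Write fragments as single-end SAM records.

    One record per fragment: POS = start, CIGAR = full-length match, mapped
    forward, with an @SQ header line for the reference. Round-trips exactly
    through :func:`nmquant.endcount.profile_from_alignments`.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.ref_id, "LN": ref.length}],
    }
    frags = np.asarray(
        [(f.start, f.end) for f in fragments]
        if fragments is not None and len(fragments) and isinstance(fragments[0], Fragment)
        else fragments,
        dtype=np.int64,
    ).reshape(-1, 2)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i, (s, e) in enumerate(frags):
            s, e = int(s), int(e)
            if not 1 <= s <= e <= ref.length:
                raise SimulationError(f"fragment ({s}, {e}) outside 1..{ref.length}")
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"frag_{i}"
            rec.reference_id = 0
            rec.reference_start = s - 1
            rec.cigarstring = f"{e - s + 1}M"
            rec.query_sequence = ref.sequence[s - 1 : e].replace("U", "T")
            rec.mapping_quality = 60
            rec.flag = 0
            out.write(rec)


def simulate_sample(
    refs: Mapping[str, RnaRef],
    sites: Sequence[NmSite],
    params: SimParams,
    rng: np.random.Generator,
) -> dict[str, CleavageProfile]:
    """One sample over the whole reference pool; molecules scale with abundance."""
    max_ab = max((r.abundance for r in refs.values()), default=0.0)
    if max_ab <= 0:
        raise SimulationError("all reference abundances are zero")
    profiles = {}
    for rid, ref in refs.items():
        n_mol = int(round(params.n_molecules * ref.abundance / max_ab))
        ref_sites = [s for s in sites if s.ref_id == rid]
        _, prof, _ = simulate_fragments(
            ref, ref_sites, replace(params, n_molecules=n_mol), rng=rng
        )
        profiles[rid] = prof
    return profiles


def simulate_condition_set(
    refs: Mapping[str, RnaRef],
    sites: Sequence[NmSite],
    design: Mapping[str, str],
    condition_stoich: Mapping[str, Mapping[tuple[str, int], float]],
    params: SimParams,
    outdir=None,
) -> tuple[dict[str, dict[str, CleavageProfile]], pd.DataFrame]:
    """Simulate a multi-sample design: ``design`` maps sample_id -> condition.

    Each sample gets an independent RNG stream derived deterministically from
    (params.seed, sample_id), so replicates differ while reruns with the same
    master seed are bit-identical. Returns per-sample profiles and a truth
    table (sample, condition, ref_id, position, stoichiometry); if ``outdir``
    is given, count tables and the truth table are written there as TSV.
    """
    for sample, cond in design.items():
        if cond not in condition_stoich:
            raise SimulationError(f"sample {sample!r} has unknown condition {cond!r}")

    all_profiles: dict[str, dict[str, CleavageProfile]] = {}
    truth_rows = []
    for sample, cond in design.items():
        sparams = replace(params, stoich=dict(condition_stoich[cond]))
        rng = _sample_seed(params.seed, sample)
        all_profiles[sample] = simulate_sample(refs, sites, sparams, rng)
        for s in sites:
            truth_rows.append(
                {
                    "sample_id": sample,
                    "condition": cond,
                    "ref_id": s.ref_id,
                    "position": s.position,
                    "stoichiometry": float(
                        condition_stoich[cond].get((s.ref_id, s.position), 0.0)
                    ),
                }
            )
    truth = pd.DataFrame(truth_rows)

    if outdir is not None:
        from .endcount import write_counts

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, profiles in all_profiles.items():
            write_counts(profiles, outdir / f"{sample}.counts.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return all_profiles, truth


def simulate_lcms(
    refs: Mapping[str, RnaRef],
    sites: Sequence[NmSite],
    stoich: Mapping[tuple[str, int], float],
    noise_cv: float,
    seed: int,
    sample_id: str = "lcms",
    condition: str = "",
) -> pd.DataFrame:
    """Noisy global nucleoside content derived from ground-truth stoichiometry.

    The exact expected content (abundance-weighted mole fraction per Nm
    species) is multiplied per species by lognormal noise with coefficient of
    variation ``noise_cv``; noise_cv = 0 reproduces the expectation exactly.
    """
    from .lcms import expected_global_content

    if noise_cv < 0:
        raise SimulationError("noise_cv must be >= 0")
    content = expected_global_content(refs, sites, stoich)
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())]))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -(sigma**2) / 2  # unit-mean lognormal
        noise = rng.lognormal(mean=mu, sigma=sigma, size=len(content))
        content = content.copy()
        content["content"] = content["content"] * noise
    out = content.copy()
    out["sample_id"] = sample_id
    out["condition"] = condition
    return out
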