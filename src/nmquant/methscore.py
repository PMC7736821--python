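"""MethScore: per-site 2'-O-methylation protection scores with coverage gating.

A 2'-O-methylated ribose protects the phosphodiester bond 3' of it from
alkaline hydrolysis, so the fragment-end count at that bond dips relative to
its neighborhood. The score at site n compares the end count e(n) to the
unweighted mean ê(n) of the 2w flanking bonds:

    score = clamp(1 - e(n) / ê(n), 0, 1)

Under uniform random cleavage this raw score has expectation equal to the
methylated fraction f, so MethScore is read as methylation stoichiometry:
~0 unmethylated, ~1 fully methylated.

Flanking bonds that are themselves candidate Nm sites are excluded from the
neighborhood by default (a heavily modified anticodon loop would otherwise
bias ê(n)); entries whose neighbor coverage falls below the gate are reported
NA with a reason, implementing the insufficient-coverage exclusion as an
explicit rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .endcount import CleavageProfile
from .refmodel import NmSite

DEFAULT_WINDOW = 2
DEFAULT_GATE = 10.0


@dataclass
class SiteScore:
    """Score of one site in one sample; ``score`` is None when gated."""

    ref_id: str
    position: int
    score: float | None
    raw: float | None
    coverage: float
    reason: str = ""  # non-empty iff score is None


@dataclass
class MethScoreTable:
    """Site x sample score matrix plus raw scores and neighbor coverage.

    ``scores`` / ``raw`` / ``coverage`` are DataFrames indexed by
    (ref_id, position) with one column per sample; gated entries are NaN in
    ``scores`` and ``raw``. ``gating`` lists every (site, sample) exclusion
    with its reason.
    """

    scores: pd.DataFrame
    raw: pd.DataFrame
    coverage: pd.DataFrame
    gating: pd.DataFrame


def methscore(
    profile: CleavageProfile,
    site: NmSite,
    window: int = DEFAULT_WINDOW,
    gate: float = DEFAULT_GATE,
    exclude_site_bonds: Sequence[int] = (),
) -> SiteScore:
    """Score one site against one cleavage profile.

    ``exclude_site_bonds`` lists 1-based bonds (other candidate Nm sites on
    the same reference) dropped from the neighborhood mean. Returns NA with a
    reason when the site is too close to a molecule edge, when the
    neighborhood is empty or uncovered, or when ê(n) is below ``gate``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = site.position
    n_bonds = profile.n_bonds
    L = n_bonds + 1
    if not (window < n < L - window):
        return SiteScore(site.ref_id, n, None, None, 0.0, reason="edge")

    excluded = set(int(b) for b in exclude_site_bonds) - {n}
    neighbors = [
        j
        for j in range(n - window, n + window + 1)
        if j != n and 1 <= j <= n_bonds and j not in excluded
    ]
    if not neighbors:
        return SiteScore(site.ref_id, n, None, None, 0.0, reason="no neighbors")

    ehat = float(np.mean([profile.counts[j - 1] for j in neighbors]))
    if ehat == 0.0:
        return SiteScore(site.ref_id, n, None, None, 0.0,
                         reason="zero neighbor coverage")
    if ehat < gate:
        return SiteScore(site.ref_id, n, None, None, ehat,
                         reason=f"coverage {ehat:.1f} below gate {gate:g}")

    raw = 1.0 - profile.counts[n - 1] / ehat
    return SiteScore(site.ref_id, n, float(min(1.0, max(0.0, raw))), float(raw), ehat)


def score_all(
    profiles_by_sample: Mapping[str, Mapping[str, CleavageProfile]],
    sites: Sequence[NmSite],
    window: int = DEFAULT_WINDOW,
    gate: float = DEFAULT_GATE,
    exclude_nm_neighbors: bool = True,
) -> MethScoreTable:
    """Score every measurable site in every sample.

    ``profiles_by_sample`` maps sample_id -> (ref_id -> profile). With
    ``exclude_nm_neighbors`` (default) the neighborhood of each site omits
    bonds belonging to other candidate sites on the same reference.
    """
    site_bonds: dict[str, list[int]] = {}
    for s in sites:
        site_bonds.setdefault(s.ref_id, []).append(s.position)

    samples = list(profiles_by_sample)
    index = pd.MultiIndex.from_tuples(
        [(s.ref_id, s.position) for s in sites], names=["ref_id", "position"]
    )
    scores = pd.DataFrame(np.nan, index=index, columns=samples)
    raw = pd.DataFrame(np.nan, index=index, columns=samples)
    coverage = pd.DataFrame(np.nan, index=index, columns=samples)
    gating_rows = []

    for sample, profiles in profiles_by_sample.items():
        for site in sites:
            prof = profiles.get(site.ref_id)
            if prof is None:
                gating_rows.append(
                    (site.ref_id, site.position, sample, "no profile for reference")
                )
                continue
            excl = site_bonds[site.ref_id] if exclude_nm_neighbors else ()
            res = methscore(prof, site, window=window, gate=gate,
                            exclude_site_bonds=excl)
            key = (site.ref_id, site.position)
            coverage.loc[key, sample] = res.coverage
            if res.score is None:
                gating_rows.append((site.ref_id, site.position, sample, res.reason))
            else:
                scores.loc[key, sample] = res.score
                raw.loc[key, sample] = res.raw

    gating = pd.DataFrame(
        gating_rows, columns=["ref_id", "position", "sample_id", "reason"]
    )
    return MethScoreTable(scores=scores, raw=raw, coverage=coverage, gating=gating)
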