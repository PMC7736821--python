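"""Global modified-nucleoside content model and cross-method comparison.

The orthogonal LC-MS axis of the analysis: per-site methylation
stoichiometries, weighted by pool abundance, determine the mole fraction of
each 2'-O-methylated nucleoside species (Gm, Cm, Um, Am) among all
nucleosides of the pool. A stress-induced stoichiometry change at D-loop
Gm18 sites therefore shows up as an increase of global Gm content, which the
sequencing-derived per-site deltas should mirror — the concordance measured
by :func:`cross_method_correlation`.

Instrument response and calibration are abstracted away: content is the
normalized mole fraction a calibrated internal-standard quantification would
report.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import ConditionDesign, welch_test
from .refmodel import NmSite, RnaRef


class ContentError(ValueError):
    pass


def species_of(site: NmSite) -> str:
    """Nm nucleoside species produced by methylating a site (base + 'm')."""
    return f"{site.base}m"


def expected_global_content(
    refs: Mapping[str, RnaRef],
    sites: Sequence[NmSite],
    stoich: Mapping[tuple[str, int], float],
) -> pd.DataFrame:
    """Exact abundance-weighted mole fraction of each Nm species.

    content(s) = sum_r a_r * sum_{sites of species s on r} f_site
                 / sum_r a_r * L_r

    i.e. the expected number of 2'-O-methylated nucleosides of species s per
    nucleoside of the pool. Linear in f; invariant to uniform rescaling of
    abundances. Species with no site in ``sites`` are absent from the output.
    """
    total = sum(r.abundance * r.length for r in refs.values())
    if total <= 0:
        raise ContentError("all reference abundances are zero")
    num: dict[str, float] = {}
    for s in sites:
        if s.ref_id not in refs:
            raise ContentError(f"site on unknown reference {s.ref_id!r}")
        f = float(stoich.get((s.ref_id, s.position), 0.0))
        if not 0 <= f <= 1:
            raise ContentError(f"stoichiometry {f} outside [0, 1]")
        sp = species_of(s)
        num[sp] = num.get(sp, 0.0) + refs[s.ref_id].abundance * f
    return pd.DataFrame(
        [{"species": sp, "content": v / total} for sp, v in sorted(num.items())],
        columns=["species", "content"],
    )


def relative_content_change(
    contents: pd.DataFrame, design: ConditionDesign, with_tests: bool = False
) -> pd.DataFrame:
    """Per-species content change of each condition versus control.

    ``contents`` is a long table (species, content, sample_id, condition) as
    produced by the LC-MS simulator, one row per species per sample. The
    change is the difference of condition means, mirroring the
    stoichiometry-point convention of the sequencing arm; Welch p-values are
    added for groups with >= 2 replicates when ``with_tests``.
    """
    if design.control not in set(contents["condition"]):
        raise ContentError(f"control condition {design.control!r} absent")
    rows = []
    for sp, block in contents.groupby("species", sort=True):
        ctrl = block.loc[block["condition"] == design.control, "content"]
        for cond in design.conditions:
            if cond == design.control:
                continue
            vals = block.loc[block["condition"] == cond, "content"]
            if vals.empty:
                continue
            row = {
                "species": sp,
                "condition": cond,
                "control_mean": float(ctrl.mean()),
                "condition_mean": float(vals.mean()),
                "delta": float(vals.mean() - ctrl.mean()),
            }
            if with_tests:
                x = vals.to_numpy(dtype=float)
                y = ctrl.to_numpy(dtype=float)
                if len(x) >= 2 and len(y) >= 2 and (x.var(ddof=1) > 0 or y.var(ddof=1) > 0):
                    _, _, row["p_welch"] = welch_test(x, y)
                else:
                    row["p_welch"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def cross_method_correlation(
    ribo_deltas, lcms_deltas
) -> tuple[float, float]:
    """Agreement between sequencing-derived and LC-MS-derived deltas.

    Both arguments are paired numeric vectors (per species or per isolated
    tRNA, same order). Returns (Pearson r, sign concordance fraction); a
    pair with a zero on either side counts as concordant. r is NaN when
    either vector has zero variance.
    """
    x = np.asarray(ribo_deltas, dtype=float)
    y = np.asarray(lcms_deltas, dtype=float)
    if len(x) != len(y):
        raise ContentError("paired vectors must have equal length")
    if len(x) < 3:
        raise ContentError("need at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    concordant = (np.sign(x) == np.sign(y)) | (x == 0) | (y == 0)
    return r, float(np.mean(concordant))
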