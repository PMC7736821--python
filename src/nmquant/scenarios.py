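"""Study-level experiments wiring the modules into the full analysis.

Each function here runs one self-contained in-silico experiment on the
packaged fixture — stoichiometry recovery, null calibration of the Welch
screen, the stress-perturbation ranking, and the sequencing/LC-MS
concordance — and returns its summary numbers. The analysis drivers and the
acceptance checks are thin wrappers over these.

The default stress scenario mirrors the study design: two conditions
(control and stress) with replicates; D-loop Gm18 sites of five responsive
isoacceptors nearly unmodified under control (f = 0.05) and strongly induced
under stress (+0.4); remaining Gm18 sites and the anticodon-loop and rRNA
sites constitutive.
"""

from __future__ import annotations

import pandas as pd

from . import fixtures
from .diffmeth import ConditionDesign, delta_vs_control, welch_test
from .lcms import cross_method_correlation, relative_content_change
from .methscore import methscore, score_all
from .refmodel import GM18, RRNA_NM, filter_measurable
from .simulate import SimParams, simulate_condition_set, simulate_fragments, simulate_lcms

#: constitutive stoichiometries by site class under both conditions
_CONSTITUTIVE = {GM18: 0.5, "Nm32": 0.8, "Nm34": 0.6, RRNA_NM: 0.9}
#: control-condition stoichiometry of the five responsive Gm18 sites
RESPONSIVE_BASELINE = 0.05
#: stress-induced stoichiometry increase at the responsive sites
RESPONSIVE_DELTA = 0.4


def measurable_sites():
    trna = [s for s in fixtures.builtin_sites() if s.site_class != RRNA_NM]
    kept, summary = filter_measurable(trna, fixtures.RARE_ISOACCEPTORS)
    return kept, summary


def site_model_summary() -> dict[str, int]:
    """Cardinalities of the packaged site model before/after exclusions."""
    sites = fixtures.builtin_sites()
    trna = [s for s in sites if s.site_class != RRNA_NM]
    kept, summary = measurable_sites()
    return {
        "candidate_trna_sites": len(trna),
        "measurable_trna_sites": len(kept),
        "measurable_gm18": summary[GM18],
        "measurable_nm32": summary["Nm32"],
        "measurable_nm34": summary["Nm34"],
        "rrna_sites": sum(s.site_class == RRNA_NM for s in sites),
    }


def stress_stoichiometries(
    responsive=fixtures.RESPONSIVE_GM18,
    baseline: float = RESPONSIVE_BASELINE,
    delta: float = RESPONSIVE_DELTA,
):
    """(control, stress) stoichiometry maps over all measurable sites."""
    kept, _ = measurable_sites()
    control, stress = {}, {}
    for s in kept:
        if s.site_class == GM18 and s.ref_id in responsive:
            control[s.key] = baseline
            stress[s.key] = baseline + delta
        else:
            f = _CONSTITUTIVE[s.site_class]
            control[s.key] = f
            stress[s.key] = f
    return control, stress


def recovery_experiment(
    seeds=(0, 1, 2),
    f_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_molecules: int = 200_000,
) -> pd.DataFrame:
    """MethScore versus known stoichiometry on one reference.

    Simulates a single Gm18 site at each stoichiometry of ``f_grid`` for each
    seed at default simulator settings and scores it; returns a long table
    (f, seed, score, error).
    """
    refs = fixtures.builtin_refs()
    ref = refs["tRNA-Ser-CGA"]
    sites = [s for s in fixtures.builtin_sites() if s.ref_id == ref.ref_id]
    site = sites[0]
    rows = []
    for seed in seeds:
        for f in f_grid:
            params = SimParams(
                n_molecules=n_molecules, seed=seed, stoich={site.key: f}
            )
            _, prof, _ = simulate_fragments(ref, sites, params)
            score = methscore(prof, site, exclude_site_bonds=[s.position for s in sites]).score
            rows.append({"f": f, "seed": seed, "score": score, "error": abs(score - f)})
    return pd.DataFrame(rows)


def _subpool(ref_ids):
    refs = fixtures.builtin_refs()
    pool = {rid: refs[rid] for rid in ref_ids}
    kept, _ = measurable_sites()
    sites = [s for s in kept if s.ref_id in pool]
    return pool, sites


def _design(n_replicates: int) -> ConditionDesign:
    assignments = {
        f"{cond}_r{r}": (cond, r)
        for cond in ("control", "stress")
        for r in range(1, n_replicates + 1)
    }
    return ConditionDesign(assignments, control="control")


def _score_condition_set(pool, sites, design, cond_stoich, params):
    sample_conditions = {s: c for s, (c, _) in design.assignments.items()}
    profiles, _ = simulate_condition_set(
        pool, sites, sample_conditions, cond_stoich, params
    )
    return score_all(profiles, sites)


def null_calibration(
    n_datasets: int = 100,
    seed: int = 0,
    n_replicates: int = 3,
    n_molecules: int = 20_000,
    f: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the per-site Welch screen under the null.

    Both conditions share identical stoichiometry maps (f at every site), so
    every positive is false. Runs ``n_datasets`` independent simulated
    datasets on a five-reference sub-pool and reports the fraction of
    site-tests with p < alpha. Tests use the raw (unclamped) scores, whose
    sampling distribution is approximately normal at mid-range f.
    """
    pool, sites = _subpool(
        ["tRNA-Ser-CGA", "tRNA-Pro-GGG", "tRNA-Thr-GGU", "tRNA-Val-UAC", "tRNA-His-GUG"]
    )
    design = _design(n_replicates)
    stoich = {s.key: f for s in sites}
    cond_stoich = {"control": stoich, "stress": stoich}
    ctrl_cols = design.samples_of("control")
    stress_cols = design.samples_of("stress")

    n_sig = 0
    n_tests = 0
    for d in range(n_datasets):
        params = SimParams(n_molecules=n_molecules, seed=seed * n_datasets + d)
        table = _score_condition_set(pool, sites, design, cond_stoich, params)
        for key in table.raw.index:
            x = table.raw.loc[key, stress_cols].dropna().to_numpy(dtype=float)
            y = table.raw.loc[key, ctrl_cols].dropna().to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                continue
            _, _, p = welch_test(x, y)
            n_tests += 1
            n_sig += p < alpha
    return {
        "false_positive_rate": n_sig / n_tests,
        "n_tests": n_tests,
        "alpha": alpha,
    }


def perturbation_experiment(
    seeds=(0, 1, 2),
    n_replicates: int = 3,
    n_molecules: int = 200_000,
    delta: float = RESPONSIVE_DELTA,
) -> pd.DataFrame:
    """Stress response ranking: do the five induced Gm18 sites lead |delta|?

    Simulates control + stress with the default scenario over all Gm18
    carrier references and, per seed, ranks measurable Gm18 sites by the
    absolute condition-versus-control MethScore delta. Returns one row per
    (seed, site) with the delta, the true delta, and the rank.
    """
    gm18_refs = [
        rid for rid in fixtures.gm18_carrier_ids()
        if rid not in fixtures.RARE_ISOACCEPTORS
    ]
    pool, all_sites = _subpool(gm18_refs)
    sites = [s for s in all_sites if s.site_class == GM18]
    design = _design(n_replicates)
    control, stress = stress_stoichiometries(delta=delta)
    cond_stoich = {"control": control, "stress": stress}

    rows = []
    for seed in seeds:
        params = SimParams(n_molecules=n_molecules, seed=seed)
        table = _score_condition_set(pool, sites, design, cond_stoich, params)
        deltas = delta_vs_control(table.scores, design)
        deltas["abs_delta"] = deltas["delta"].abs()
        deltas = deltas.sort_values("abs_delta", ascending=False).reset_index(drop=True)
        for rank, row in deltas.iterrows():
            key = (row["ref_id"], row["position"])
            rows.append(
                {
                    "seed": seed,
                    "ref_id": row["ref_id"],
                    "position": row["position"],
                    "delta": row["delta"],
                    "true_delta": stress[key] - control[key],
                    "rank": rank + 1,
                    "responsive": row["ref_id"] in fixtures.RESPONSIVE_GM18,
                }
            )
    return pd.DataFrame(rows)


def concordance_experiment(
    seeds=(0, 1, 2),
    n_replicates: int = 2,
    n_molecules: int = 200_000,
    noise_cv: float = 0.05,
    isolated_refs=(
        "tRNA-Leu-cmnm5UmAA",
        "tRNA-Ser-CGA",
        "tRNA-Pro-GGG",
        "tRNA-Arg-ICG",
        "tRNA-Gly-GCC",
        "tRNA-Thr-GGU",
        "tRNA-Val-UAC",
    ),
) -> pd.DataFrame:
    """Sequencing-arm versus LC-MS-arm Gm deltas per isolated tRNA.

    For each seed, the sequencing arm simulates control + stress over the
    isolated references and takes the per-Gm18-site MethScore delta; the
    LC-MS arm computes each isolated tRNA's noisy global Gm content under
    both conditions and takes the content delta. Returns one row per seed
    with the Pearson r and sign-concordance over the isolated tRNAs.
    """
    pool, all_sites = _subpool(list(isolated_refs))
    design = _design(n_replicates)
    control, stress = stress_stoichiometries()
    cond_stoich = {"control": control, "stress": stress}

    rows = []
    for seed in seeds:
        params = SimParams(n_molecules=n_molecules, seed=seed)
        table = _score_condition_set(pool, all_sites, design, cond_stoich, params)
        seq_deltas = delta_vs_control(table.scores, design)
        seq_gm = seq_deltas[seq_deltas["position"] == 18].set_index("ref_id")["delta"]

        lcms_gm = {}
        for rid in isolated_refs:
            single = {rid: pool[rid]}
            ssites = [s for s in all_sites if s.ref_id == rid]
            per_cond = {}
            for cond, stoich in cond_stoich.items():
                vals = [
                    simulate_lcms(
                        single, ssites, stoich, noise_cv=noise_cv,
                        seed=seed, sample_id=f"{rid}_{cond}_r{r}", condition=cond,
                    )
                    for r in range(1, n_replicates + 1)
                ]
                frame = pd.concat(vals, ignore_index=True)
                gm = frame.loc[frame["species"] == "Gm", "content"]
                per_cond[cond] = float(gm.mean()) if len(gm) else 0.0
            lcms_gm[rid] = per_cond["stress"] - per_cond["control"]

        paired = [(seq_gm.loc[rid], lcms_gm[rid]) for rid in isolated_refs]
        x, y = zip(*paired)
        r, conc = cross_method_correlation(x, y)
        rows.append({"seed": seed, "pearson_r": r, "sign_concordance": conc,
                     "n_trnas": len(paired)})
    return pd.DataFrame(rows)
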