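"""Hydrolysis simulator: protection, fragment statistics, determinism, SAM."""

import numpy as np
import pytest

from nmquant.endcount import profile_from_alignments
from nmquant.refmodel import GM18, NmSite
from nmquant.simulate import (
    SimParams,
    SimulationError,
    simulate_condition_set,
    simulate_fragments,
    simulate_lcms,
    emit_sam,
)


def run_length_oracle(L, q):
    """Expected fragment count and mean length by direct enumeration.

    A fragment (s, e) requires a cut at bond s-1 (or s = 1), a cut at bond e
    (or e = L) and no cut at bonds s..e-1; lengths are geometric truncated
    at L. Exact, Monte-Carlo-free.
    """
    total_p = 0.0
    total_len = 0.0
    for s in range(1, L + 1):
        for e in range(s, L + 1):
            p = (q if s > 1 else 1.0) * (q if e < L else 1.0) * (1 - q) ** (e - s)
            total_p += p
            total_len += (e - s + 1) * p
    return total_p, total_len / total_p


class TestFragmentation:
    def test_full_methylation_protects_exactly(self, small_ref, small_site):
        params = SimParams(
            n_molecules=5000, seed=3, stoich={(small_ref.ref_id, 30): 1.0}
        )
        _, prof, _ = simulate_fragments(small_ref, [small_site], params)
        assert prof.bond(30) == 0

    def test_certain_cleavage_is_uniform(self, small_ref):
        # q = 1 with no sites: every bond cut in every molecule, so every
        # internal bond collects exactly one 5' and one 3' boundary event.
        n = 500
        params = SimParams(
            cleavage_prob=1.0, n_molecules=n, size_min=1, size_max=60, seed=5
        )
        _, prof, _ = simulate_fragments(small_ref, [], params)
        assert set(prof.counts.tolist()) == {2 * n}

    def test_mean_fragment_length_matches_enumeration(self, small_ref):
        q = 0.05
        L = small_ref.length
        params = SimParams(
            cleavage_prob=q, n_molecules=100_000, size_min=1, size_max=L, seed=9
        )
        frags, _, _ = simulate_fragments(small_ref, [], params)
        lengths = frags[:, 1] - frags[:, 0] + 1
        _, expected_mean = run_length_oracle(L, q)
        assert abs(lengths.mean() - expected_mean) / expected_mean < 0.02

    def test_length_conservation_without_size_selection(self, small_ref):
        n = 2000
        params = SimParams(n_molecules=n, size_min=1, size_max=small_ref.length, seed=2)
        frags, _, _ = simulate_fragments(small_ref, [], params)
        assert (frags[:, 1] - frags[:, 0] + 1).sum() == n * small_ref.length

    def test_zero_molecules_empty_outputs(self, small_ref, small_site):
        params = SimParams(n_molecules=0)
        frags, prof, truth = simulate_fragments(small_ref, [small_site], params)
        assert len(frags) == 0
        assert prof.counts.sum() == 0
        assert truth == {(small_ref.ref_id, 30): 0.0}

    def test_invalid_stoichiometry_rejected(self):
        with pytest.raises(SimulationError, match="outside"):
            SimParams(stoich={("x", 1): 1.5})

    def test_foreign_site_rejected(self, small_ref, fast_params):
        alien = NmSite("other", 5, "18", "G", "Gm18", GM18)
        with pytest.raises(SimulationError, match="not on"):
            simulate_fragments(small_ref, [alien], fast_params)

    def test_determinism(self, small_ref, small_site, fast_params):
        a = simulate_fragments(small_ref, [small_site], fast_params)
        b = simulate_fragments(small_ref, [small_site], fast_params)
        assert np.array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestEmitSam:
    def test_record_coordinates(self, small_ref, tmp_path):
        sam = tmp_path / "out.sam"
        emit_sam(np.array([[5, 14]]), small_ref, sam)
        text = sam.read_text().splitlines()
        assert any(l.startswith("@SQ") and f"LN:{small_ref.length}" in l for l in text)
        rec = [l for l in text if not l.startswith("@")][0].split("\t")
        assert rec[3] == "5"  # POS
        assert rec[5] == "10M"  # full-length match CIGAR

    def test_empty_fragment_list(self, small_ref, tmp_path):
        sam = tmp_path / "out.sam"
        emit_sam(np.empty((0, 2)), small_ref, sam)
        assert all(l.startswith("@") for l in sam.read_text().splitlines())

    def test_round_trip_equals_simulator_profile(self, small_ref, fast_params, tmp_path):
        frags, prof, _ = simulate_fragments(small_ref, [], fast_params)
        sam = tmp_path / "sim.sam"
        emit_sam(frags[:1000], small_ref, sam)
        from nmquant.endcount import profile_from_fragments

        expected = profile_from_fragments(frags[:1000], small_ref)
        got = profile_from_alignments(sam, {small_ref.ref_id: small_ref})
        assert got[small_ref.ref_id] == expected


class TestConditionSet:
    def make_design(self):
        return {f"{c}_r{i}": c for c in ("control", "stress") for i in (1, 2)}

    def test_unknown_condition_rejected(self, builtin_refs, builtin_sites, fast_params):
        with pytest.raises(SimulationError, match="unknown condition"):
            simulate_condition_set(
                builtin_refs, builtin_sites, {"s1": "mystery"}, {"control": {}},
                fast_params,
            )

    def test_replicates_differ_but_rerun_is_identical(self, small_ref, small_site, fast_params):
        refs = {small_ref.ref_id: small_ref}
        stoich = {"control": {(small_ref.ref_id, 30): 0.5}}
        design = {"control_r1": "control", "control_r2": "control"}
        profs1, truth1 = simulate_condition_set(refs, [small_site], design, stoich, fast_params)
        profs2, truth2 = simulate_condition_set(refs, [small_site], design, stoich, fast_params)
        assert not np.array_equal(
            profs1["control_r1"][small_ref.ref_id].counts,
            profs1["control_r2"][small_ref.ref_id].counts,
        )
        assert profs1["control_r1"][small_ref.ref_id] == profs2["control_r1"][small_ref.ref_id]
        assert truth1.equals(truth2)

    def test_truth_table_written(self, small_ref, small_site, fast_params, tmp_path):
        refs = {small_ref.ref_id: small_ref}
        stoich = {"control": {(small_ref.ref_id, 30): 0.25}}
        _, truth = simulate_condition_set(
            refs, [small_site], {"s1": "control"}, stoich, fast_params, outdir=tmp_path
        )
        assert (tmp_path / "truth.tsv").exists()
        assert (tmp_path / "s1.counts.tsv").exists()
        assert truth.loc[0, "stoichiometry"] == 0.25


class TestLcmsSimulator:
    def test_zero_noise_is_exact(self, builtin_refs, builtin_sites):
        from nmquant.lcms import expected_global_content

        stoich = {(s.ref_id, s.position): 0.5 for s in builtin_sites}
        got = simulate_lcms(builtin_refs, builtin_sites, stoich, noise_cv=0.0, seed=1)
        exp = expected_global_content(builtin_refs, builtin_sites, stoich)
        assert np.allclose(got["content"].to_numpy(), exp["content"].to_numpy())

    def test_zero_stoichiometry_is_zero_regardless_of_noise(self, builtin_refs, builtin_sites):
        got = simulate_lcms(builtin_refs, builtin_sites, {}, noise_cv=0.5, seed=1)
        assert (got["content"] == 0).all()

    def test_empirical_cv_matches_noise_model(self, builtin_refs, builtin_sites):
        stoich = {(s.ref_id, s.position): 0.5 for s in builtin_sites}
        reps = np.array(
            [
                simulate_lcms(
                    builtin_refs, builtin_sites, stoich, noise_cv=0.1, seed=4,
                    sample_id=f"r{i}",
                )["content"].to_numpy()
                for i in range(100)
            ]
        )
        cv = reps.std(axis=0, ddof=1) / reps.mean(axis=0)
        assert np.all(np.abs(cv - 0.1) < 0.03)
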