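"""Factorial comparison, family pooling, BMA and the automatic search."""

import numpy as np
import pytest

from facedcm.cohort import (make_ground_truth, sample_covariates,
                            simulate_subject_posteriors)
from facedcm.peb import (PEB, BMAResult, GroupDesign, PEBResults,
                         family_inference, threshold_parameters)

COVS = ("commonality", "LI_FFA", "LI_OFA")


@pytest.fixture(scope="module")
def uninformative_result(spec):
    """A PEB result whose posterior equals its prior: every reduced model
    has identical evidence."""
    cov = sample_covariates(8, 0)
    gt = make_ground_truth(spec, cov, 0)
    posts = simulate_subject_posteriors(gt, spec, rng=0)
    peb = PEB(posts, GroupDesign.from_covariates(cov))
    m = len(peb.cell_names)
    from facedcm.peb import BETA_PRIOR_VAR

    return PEBResults(model=peb, beta_mean=np.zeros(m),
                      beta_cov=BETA_PRIOR_VAR * np.eye(m),
                      free_energy=0.0, gamma=0.0)


class TestComparisonNormalization:
    def test_flat_evidence_gives_uniform_marginals(self, uninformative_result,
                                                   factorial_space):
        comp = uninformative_result.compare(factorial_space, COVS,
                                            compute_bma=False)
        for cov in COVS:
            assert np.allclose(comp.marginal_pp[cov], 1.0 / 37.0, atol=1e-10)

    def test_marginals_sum_to_one(self, recovery_runs):
        comp = recovery_runs[0]["comparison"]
        for cov in comp.covariates:
            assert comp.marginal_pp[cov].sum() == pytest.approx(1.0,
                                                                abs=1e-10)
        assert comp.joint_pp.sum() == pytest.approx(1.0, abs=1e-10)

    def test_marginals_consistent_with_joint(self, recovery_runs):
        comp = recovery_runs[0]["comparison"]
        joint = comp.joint_pp
        assert np.allclose(comp.marginal_pp["commonality"],
                           joint.sum(axis=(1, 2)), atol=1e-12)
        assert np.allclose(comp.marginal_pp["LI_OFA"],
                           joint.sum(axis=(0, 1)), atol=1e-12)

    def test_joint_covers_all_combinations(self, recovery_runs):
        comp = recovery_runs[0]["comparison"]
        assert comp.joint_log_evidence.size == 37 ** 3 == 50_653

    def test_family_pp_sums_member_pp(self, recovery_runs):
        comp = recovery_runs[0]["comparison"]
        fam = family_inference(comp, "type")
        for cov in comp.covariates:
            assert fam[cov].sum() == pytest.approx(1.0, abs=1e-9)
        uniform = np.full(37, 1.0 / 37.0)
        sizes = {f: len(idx)
                 for f, idx in comp.space.families("type").items()}
        assert sum(sizes.values()) == 37

    def test_point_mass_model_dominates_families(self, uninformative_result,
                                                 factorial_space):
        comp = uninformative_result.compare(factorial_space, COVS,
                                            compute_bma=False)
        # overwrite with a synthetic point mass on model 15-analogue
        target = next(i for i, m in enumerate(factorial_space.models)
                      if (m.hemisphere, m.region, m.ctype)
                      == ("LEFT", "OFA", "SELF"))
        comp.marginal_pp["LI_FFA"] = np.eye(37)[target]
        fam = family_inference(comp, "type")
        assert fam.loc["SELF", "LI_FFA"] == pytest.approx(1.0)
        fam_h = family_inference(comp, "hemisphere")
        assert fam_h.loc["LEFT", "LI_FFA"] == pytest.approx(1.0)


class TestModelRecovery:
    def test_li_ffa_modal_winner_is_left_ofa_self(self, recovery_runs):
        """(LEFT, OFA, SELF) is the most frequent LI_FFA winner across
        seeds, and runner-up winners are always SELF-containing supersets
        of the planted cell."""
        from collections import Counter

        winners = Counter()
        for run in recovery_runs:
            model, _ = run["comparison"].winner("LI_FFA")
            winners[(model.hemisphere, model.region, model.ctype)] += 1
            idx = run["comparison"].space.parameter_names.index(
                "B(faces):lOFA->lOFA")
            assert model.mask[idx]  # the planted cell is always in the winner
        assert winners.most_common(1)[0][0] == ("LEFT", "OFA", "SELF")

    def test_li_ffa_effect_always_detected(self, recovery_runs):
        """The null family never explains the planted LI_FFA effect."""
        for run in recovery_runs:
            fam = family_inference(run["comparison"], "type")
            assert fam.loc["NONE", "LI_FFA"] < 0.05
            fam_h = family_inference(run["comparison"], "hemisphere")
            assert fam_h.loc["LEFT", "LI_FFA"] > \
                fam_h.loc["RIGHT", "LI_FFA"]

    def test_commonality_winner_is_full_model(self, recovery_runs):
        wins = 0
        for run in recovery_runs:
            model, pp = run["comparison"].winner("commonality")
            wins += model.name == "ALL/BOTH/BOTH" and pp > 0.9
        assert wins >= 8

    def test_self_family_explains_li_ffa_on_average(self, recovery_runs):
        pps = [family_inference(run["comparison"], "type").loc["SELF",
                                                               "LI_FFA"]
               for run in recovery_runs]
        assert np.mean(pps) > 0.75
        assert np.median(pps) > 0.85

    def test_base_family_explains_li_ofa_on_average(self, recovery_runs):
        pps = [family_inference(run["comparison"], "type").loc["BASE",
                                                               "LI_OFA"]
               for run in recovery_runs]
        assert np.mean(pps) > 0.75

    def test_planted_signs_recovered_in_bma(self, recovery_runs):
        """Signs of planted non-zero cells recovered in >= 90% of cells
        across seeds."""
        hits = total = 0
        for run in recovery_runs:
            gt = run["gt"]
            bma = run["comparison"].bma
            est = dict(zip(bma.cell_names, bma.mean))
            for j, reg in enumerate(gt.regressor_names):
                for p, nm in enumerate(gt.parameter_names):
                    if gt.beta[j, p] == 0 or not nm.startswith("B("):
                        continue
                    total += 1
                    hits += np.sign(est[f"{reg}:{nm}"]) == np.sign(gt.beta[j, p])
        assert hits >= 0.9 * total


class TestAutomaticSearch:
    def test_final_bma_covers_256_models(self, recovery_runs):
        for run in recovery_runs:
            assert run["search"].n_final_models == 256

    def test_planted_interhemispheric_cells_survive(self, recovery_runs):
        """The opposite-signed LI_OFA effects on lFFA<->rFFA survive the
        search with Pp(nonzero) > 0.75 in >= 8/10 seeds."""
        wins = 0
        for run in recovery_runs:
            pp = dict(zip(run["search"].cell_names,
                          run["search"].bma.pp_nonzero))
            wins += (pp["LI_OFA:B(faces):lFFA->rFFA"] > 0.75
                     and pp["LI_OFA:B(faces):rFFA->lFFA"] > 0.75)
        assert wins >= 8

    def test_null_covariates_pruned(self, spec):
        """With all covariate effects zero, the search prunes the covariate
        cells while keeping commonality cells, in >= 8/10 seeds."""
        from facedcm.cohort import default_beta

        wins = 0
        for seed in range(10):
            cov = sample_covariates(30, 200 + seed)
            beta = default_beta(spec)
            beta[1:] = 0.0  # no covariate effects at all
            gt = make_ground_truth(spec, cov, 200 + seed, beta=beta)
            posts = simulate_subject_posteriors(gt, spec, obs_sd=0.15,
                                                rng=200 + seed)
            res = PEB(posts, GroupDesign.from_covariates(cov)).fit()
            search = res.search()
            pp = dict(zip(search.cell_names, search.bma.pp_nonzero))
            cov_on = [v for c, v in pp.items()
                      if not c.startswith("commonality:")]
            common_on = [v for c, v in pp.items()
                         if c.startswith("commonality:")]
            wins += (np.mean([v > 0.75 for v in cov_on]) < 0.1
                     and np.mean([v > 0.75 for v in common_on]) > 0.8)
        assert wins >= 8

    def test_search_free_energy_path_monotone(self, recovery_runs):
        for run in recovery_runs:
            path = np.asarray(run["search"].free_energy_path)
            assert np.all(np.diff(path) >= -1e-9)


class TestThresholding:
    def test_boundary_strictly_above(self):
        bma = BMAResult(cell_names=["a", "b", "c"],
                        mean=np.array([1.0, 1.0, 0.0]),
                        sd=np.ones(3),
                        pp_nonzero=np.array([0.76, 0.75, 0.10]),
                        n_models=2)
        tab = threshold_parameters(bma, 0.75)
        assert tab.flagged.tolist() == [True, False, False]

    def test_invalid_threshold_rejected(self):
        bma = BMAResult(cell_names=["a"], mean=np.zeros(1), sd=np.ones(1),
                        pp_nonzero=np.zeros(1), n_models=1)
        with pytest.raises(ValueError):
            bma.flagged(1.5)

    def test_zero_effect_bma_flags_nothing(self, uninformative_result,
                                           factorial_space):
        comp = uninformative_result.compare(factorial_space, COVS,
                                            compute_bma=True)
        covariate_cells = [i for i, c in enumerate(comp.bma.cell_names)
                           if c.split(":", 1)[0] in ("LI_FFA", "LI_OFA")
                           and "B(faces)" in c]
        flags = comp.bma.flagged(0.75)
        assert not flags[covariate_cells].any()

    def test_flagged_superset_of_planted(self, recovery_runs):
        """At threshold 0.75 the flagged set contains the planted non-zero
        covariate cells in >= 8/10 seeds."""
        wins = 0
        for run in recovery_runs:
            gt = run["gt"]
            bma = run["comparison"].bma
            flags = dict(zip(bma.cell_names, bma.flagged(0.75)))
            planted = [f"{reg}:{nm}"
                       for reg, nm in gt.nonzero_covariate_cells()]
            wins += all(flags[c] for c in planted)
        assert wins >= 8
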