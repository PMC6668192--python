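"""Partial-likelihood fitters against brute-force and external oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from crbias import (
    HazardParams,
    PopulationParams,
    SurvivalSample,
    cox_cause_specific,
    fine_gray,
    generate_confounded_covariates,
    simulate_events,
)
from crbias.estimators import DegenerateDataError, NonIdentifiableError

from conftest import random_competing_sample


def brute_force_coef(t, delta, z, event, model):
    """Maximise the explicit partial likelihood by bounded 1-d search.

    Independent of the Newton implementation: risk sets are built directly
    from their definitions, one event at a time.
    """
    t, delta, z = np.asarray(t, float), np.asarray(delta), np.asarray(z)

    def negll(b):
        ll = 0.0
        for j in np.where(delta == event)[0]:
            if model == "cox":
                rs = t >= t[j]
            else:  # subdistribution: competing-event subjects stay forever
                rs = (t >= t[j]) | (delta != event)
            ll += b * z[j] - np.log(np.sum(np.exp(b * z[rs])))
        return -ll

    res = minimize_scalar(negll, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


WORKED_SET = dict(
    t=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    delta=[1, 1, 2, 1, 2, 1],
    z=[1, 0, 1, 1, 0, 0],
)


class TestWorkedExample:
    @pytest.mark.parametrize("model,fitter", [("cox", cox_cause_specific),
                                              ("fg", fine_gray)])
    def test_six_subject_set_matches_brute_force(self, model, fitter):
        s = SurvivalSample(**WORKED_SET)
        res = fitter(s, 1)
        oracle = brute_force_coef(s.t, s.delta, s.z, 1, model)
        assert res.coef == pytest.approx(oracle, abs=1e-6)
        assert res.converged and res.se > 0 and res.n_events == 4

    def test_fine_gray_risk_set_is_larger(self):
        # subjects 3 and 5 (competing events) stay in the FG risk set, so the
        # two models genuinely differ on this data
        s = SurvivalSample(**WORKED_SET)
        assert fine_gray(s, 1).coef != pytest.approx(
            cox_cause_specific(s, 1).coef, abs=1e-3
        )


class TestRandomDatasetOracle:
    @pytest.mark.parametrize("event", [1, 2])
    def test_twenty_random_small_datasets(self, rng, event):
        checked = 0
        while checked < 20:
            t, delta, z = random_competing_sample(rng, int(rng.integers(6, 13)),
                                                  event=event)
            s = SurvivalSample(t=t, delta=delta, z=z)
            oracle_cox = brute_force_coef(t, delta, z, event, "cox")
            oracle_fg = brute_force_coef(t, delta, z, event, "fg")
            if max(abs(oracle_cox), abs(oracle_fg)) > 8:
                continue  # near-separation: MLE effectively unbounded
            assert cox_cause_specific(s, event).coef == pytest.approx(
                oracle_cox, abs=1e-6
            )
            assert fine_gray(s, event).coef == pytest.approx(oracle_fg, abs=1e-6)
            checked += 1


class TestDegenerateInputs:
    def test_single_arm_not_identifiable(self):
        s = SurvivalSample(t=[1, 2, 3], delta=[1, 2, 1], z=[1, 1, 1])
        with pytest.raises(NonIdentifiableError):
            cox_cause_specific(s, 1)
        with pytest.raises(NonIdentifiableError):
            fine_gray(s, 1)

    def test_no_events_of_requested_type(self):
        s = SurvivalSample(t=[1, 2, 3], delta=[1, 1, 1], z=[0, 1, 0])
        with pytest.raises(DegenerateDataError):
            fine_gray(s, 2)


class TestModelRelationships:
    def test_fine_gray_equals_cox_without_competing_events(self, rng):
        t = rng.exponential(size=40)
        z = rng.integers(0, 2, size=40)
        s = SurvivalSample(t=t, delta=np.ones(40, dtype=int), z=z)
        assert fine_gray(s, 1).coef == pytest.approx(
            cox_cause_specific(s, 1).coef, abs=1e-12
        )

    def test_competing_events_matter_in_fine_gray(self, rng):
        # dropping competing-event subjects entirely changes the FG fit:
        # the risk-set retention is genuinely exercised
        t, delta, z = random_competing_sample(rng, 200)
        full = fine_gray(SurvivalSample(t=t, delta=delta, z=z), 1)
        keep = delta == 1
        reduced = fine_gray(
            SurvivalSample(t=t[keep], delta=delta[keep], z=z[keep]), 1
        )
        assert abs(full.coef - reduced.coef) > 1e-3

    def test_event_label_swap_symmetry(self, rng):
        # swapping delta labels swaps which model each event's fit sees
        t, delta, z = random_competing_sample(rng, 150)
        s = SurvivalSample(t=t, delta=delta, z=z)
        swapped = SurvivalSample(t=t, delta=np.where(delta == 1, 2, 1), z=z)
        for fitter in (cox_cause_specific, fine_gray):
            assert fitter(s, 1).coef == pytest.approx(fitter(swapped, 2).coef,
                                                      abs=1e-12)
            assert fitter(s, 2).coef == pytest.approx(fitter(swapped, 1).coef,
                                                      abs=1e-12)


class TestLargeSampleBehaviour:
    def test_unconfounded_fit_recovers_treatment_effect(self):
        # correct specification for the cause-specific model: gamma1 = -1
        pop = generate_confounded_covariates(
            PopulationParams(n=50_000, rho=0.0, pi=0.5, seed=21)
        )
        ev = simulate_events(pop, HazardParams(0, 0, -1.0, 0.0, k=1.0), seed=22)
        res = cox_cause_specific(SurvivalSample.from_simulation(pop, ev), 1)
        assert abs(res.coef - (-1.0)) < 3 * res.se

    def test_null_fits_are_null(self):
        pop = generate_confounded_covariates(
            PopulationParams(n=50_000, rho=0.0, pi=0.5, seed=23)
        )
        ev = simulate_events(pop, HazardParams(0, 0, 0, 0, k=1.0), seed=24)
        s = SurvivalSample.from_simulation(pop, ev)
        for event in (1, 2):
            res = fine_gray(s, event)
            assert abs(res.coef) < 3 * res.se


class TestExternalCrossChecks:
    """Agreement with established survival software (oracles, not dependencies)."""

    def test_cox_matches_lifelines(self, rng):
        # lifelines' own stopping rule leaves ~1e-5 slack around the optimum,
        # so the comparison is at that level; the exact 1e-6 agreement is
        # checked against R's survival::coxph below
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        for _ in range(20):
            t, delta, z = random_competing_sample(rng, 80)
            s = SurvivalSample(t=t, delta=delta, z=z)
            cph = lifelines.CoxPHFitter()
            cph.fit(
                pd.DataFrame({"t": t, "e": (delta == 1).astype(int), "z": z}),
                duration_col="t",
                event_col="e",
                fit_options={"precision": 1e-9},
            )
            assert cox_cause_specific(s, 1).coef == pytest.approx(
                float(cph.params_["z"]), abs=5e-5
            )

    def test_cox_matches_r_survival(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: survival cross-check cannot run")
        import pandas as pd

        script = tmp_path / "coxph.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(survival))
                d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
                f <- coxph(Surv(t, e) ~ z, data=d, ties="breslow",
                           control=coxph.control(eps=1e-12, iter.max=100))
                cat(sprintf("%.10f", coef(f)))
                """
            )
        )
        for i in range(5):
            t, delta, z = random_competing_sample(rng, 120)
            csv = tmp_path / f"c{i}.csv"
            pd.DataFrame(
                {"t": t, "e": (delta == 1).astype(int), "z": z}
            ).to_csv(csv, index=False)
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script), str(csv)],
                capture_output=True,
                text=True,
                check=True,
            )
            ours = cox_cause_specific(SurvivalSample(t=t, delta=delta, z=z), 1).coef
            assert ours == pytest.approx(float(out.stdout), abs=1e-6)

    def test_fine_gray_matches_cmprsk(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: cmprsk cross-check cannot run")
        import pandas as pd

        script = tmp_path / "crr.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(cmprsk))
                d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
                f <- crr(d$t, d$delta, cov1=matrix(d$z, ncol=1),
                         failcode=1, cencode=0, gtol=1e-10)
                cat(sprintf("%.10f", f$coef))
                """
            )
        )
        for i in range(5):
            t, delta, z = random_competing_sample(rng, 120)
            csv = tmp_path / f"d{i}.csv"
            pd.DataFrame({"t": t, "delta": delta, "z": z}).to_csv(csv, index=False)
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script), str(csv)],
                capture_output=True,
                text=True,
                check=True,
            )
            ours = fine_gray(SurvivalSample(t=t, delta=delta, z=z), 1).coef
            assert ours == pytest.approx(float(out.stdout), abs=1e-5)
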