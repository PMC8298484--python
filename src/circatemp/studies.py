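"""Parameter- and structure-recovery simulation studies.

Because the reference cohort is not public, the pipeline is validated by
recovery: cohorts are generated at the fixture parameter values and each
stage must give back what was put in — cosinor parameters, cluster
structure and sizes, DSP prevalence, and logistic effect sizes — within
Monte-Carlo tolerance.  These studies are used both by the acceptance
script and by the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from ._utils import check_seed
from .clustering import dft_features, pam_cluster
from .cosinor import estimate_period
from .inference import bootstrap_ci, group_compare_continuous, logistic_outcome
from .preprocessing import harmonize_start, impute_missing
from .simulate import generate_cohort, generate_series
from .sleep import classify_dsp
from .specs import ArchetypeSpec, NoiseSpec, default_archetypes

__all__ = [
    "cosinor_recovery_study",
    "cluster_recovery_study",
    "dsp_recovery_study",
    "or_recovery_study",
    "bootstrap_coverage_study",
    "omnibus_calibration_study",
]


def cosinor_recovery_study(
    archetype: ArchetypeSpec,
    n_series: int = 200,
    seed: int = 11,
    marginal_sd: float = 0.4,
) -> pd.DataFrame:
    """Fit the iterative-period cosinor to ``n_series`` 48-h synthetic series.

    Noise is AR(1) (phi 0.9) with the innovation SD chosen so the marginal
    noise SD equals ``marginal_sd``; no transient or missingness, so the fits
    isolate estimator behaviour.  Returns one row of estimates per series.
    """
    noise = NoiseSpec.from_marginal_sd(
        marginal_sd, transient_magnitude=0.0, missing_fraction=0.0
    )
    sub_seeds = np.random.SeedSequence(check_seed(seed)).generate_state(n_series)
    rows = []
    for s in sub_seeds:
        rec = generate_series(archetype, noise, seed=int(s % 2**31), n_minutes=2880)
        fit = estimate_period(rec.values)
        rows.append(
            {
                "mesor": fit.mesor, "amplitude": fit.amplitude, "period": fit.period,
                "true_mesor": rec.truth["mesor"], "true_amplitude": rec.truth["amplitude"],
                "true_period": rec.truth["period"],
            }
        )
    return pd.DataFrame(rows)


def cluster_recovery_study(seed: int = 16, sigma: float = 0.1) -> dict:
    """Recover the three-archetype structure on a full-size low-noise cohort.

    Generates the default cohort (fixture per-cluster counts), harmonizes and
    imputes, extracts Fourier features (H = 24) and partitions with PAM at
    k = 3.  Reports cluster sizes and agreement with the generating labels.
    """
    bundle = generate_cohort(default_archetypes(), NoiseSpec(sigma=sigma), seed=seed)
    series = [harmonize_start(r) for r in bundle.recordings]
    matrix = impute_missing(np.vstack([s.values for s in series]), ncp=2)
    features = dft_features(matrix, H=24)
    solution = pam_cluster(features, 3, seed=seed)
    truth = bundle.truth["label"].to_numpy()
    sizes = np.bincount(solution.labels)
    return {
        "sizes": sorted(sizes.tolist(), reverse=True),
        "largest": int(sizes.max()),
        "ari": float(adjusted_rand_score(truth, solution.labels)),
        "n": bundle.n_subjects,
    }


def dsp_recovery_study(seed: int = 15) -> dict:
    """Per-cluster DSP rates recovered by the onset rule on generated sleep."""
    bundle = generate_cohort(default_archetypes(), seed=seed)
    pred = {
        sid: classify_dsp(ep) for sid, ep in bundle.sleep.groupby("subject_id")
    }
    truth = bundle.truth.set_index("subject_id")
    out = {}
    for label, grp in truth.groupby("label"):
        rates = [pred[sid] for sid in grp.index]
        out[label] = {"rate": float(np.mean(rates)), "n": len(rates)}
    return out


def or_recovery_study(
    n_replicates: int = 200,
    n: int = 281,
    log_or: float = float(np.log(0.34)),
    seed: int = 17,
) -> dict:
    """Median amplitude odds ratio over replicate logistic cohorts.

    Amplitudes are resampled from the empirical distribution of realized
    amplitudes in a default cohort, standardized, and DSP is drawn from a
    logistic model with slope ``log_or`` per SD and 50 % prevalence.
    """
    bundle = generate_cohort(default_archetypes(), NoiseSpec(sigma=0.0), seed=seed)
    pool = bundle.truth["amplitude"].to_numpy()
    rng = np.random.default_rng(check_seed(seed))
    ors = []
    for _ in range(n_replicates):
        z = rng.choice(pool, size=n, replace=True)
        z = (z - z.mean()) / z.std()
        p = 1.0 / (1.0 + np.exp(-(log_or * z)))
        y = (rng.random(n) < p).astype(float)
        res = logistic_outcome(y, pd.DataFrame({"amplitude": z}), b_ci=0, seed=1)
        if res["estimable"]:
            ors.append(res["odds_ratios"]["amplitude"])
    return {"median_or": float(np.median(ors)), "n_replicates": len(ors), "n": n}


def bootstrap_coverage_study(
    n_sim: int = 1000, n: int = 50, B: int = 1000, seed: int = 19
) -> dict:
    """Coverage of the 95 % BC bootstrap interval for a normal mean."""
    rng = np.random.default_rng(check_seed(seed))
    hits = 0
    for s in range(n_sim):
        x = rng.normal(0.0, 1.0, n)
        ci = bootstrap_ci(x, np.mean, B=B, seed=seed + s)
        hits += ci.lower <= 0.0 <= ci.upper
    return {"coverage": hits / n_sim, "n_sim": n_sim, "n": n, "B": B}


def omnibus_calibration_study(
    n_sim: int = 500, n_per_group: int = 20, b_p: int = 500, seed: int = 23
) -> dict:
    """Uniformity of omnibus bootstrap p-values under a true null."""
    rng = np.random.default_rng(check_seed(seed))
    labels = np.repeat([0, 1, 2], n_per_group)
    ps = []
    for s in range(n_sim):
        y = rng.normal(size=len(labels))
        res = group_compare_continuous(
            y, rng.permutation(labels), b_ci=100, b_p=b_p, seed=seed + s
        )
        ps.append(res["p_omnibus"])
    ks = kstest(ps, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "frac_below_05": float(np.mean(np.asarray(ps) <= 0.05)),
        "n_sim": n_sim,
    }
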