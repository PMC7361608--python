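"""End-to-end validation routines for the planted-faction pipeline.

These functions re-run whole stages of the analysis on synthetic cohorts and
summarize how well the planted structure is recovered: projection agreement
with naive reference implementations, faction recovery by connected
components, bridging-edge trajectories across waves, confidence-interval
coverage and reliability checks. They power the reproduction script and the
acceptance test suite.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort import ATTENTION_EXPECTED, SyntheticConfig, generate_cohort
from .factions import UNASSIGNED, connected_components
from .network import (StanceMatrix, binarize, bridging_edge_count,
                      project_attitudes, project_participants)
from .reference import project_attitudes_naive, project_participants_naive
from .stats import eta_sq_ci, logistic_fit, oneway_anova
from .survey import apply_attention_exclusions, match_waves

__all__ = [
    "random_stance_matrix",
    "projection_oracle_agreement",
    "run_planted_pipeline",
    "planted_recovery_summary",
    "eta_ci_coverage",
    "logistic_recovery",
]


def random_stance_matrix(rng: np.random.Generator, n: int = 20, k: int = 8,
                         p_missing: float = 0.1, p_neutral: float = 0.15) -> StanceMatrix:
    """Random trichotomized stance matrix with missing cells and neutrals."""
    signs = rng.choice([-1.0, 1.0], size=(n, k))
    u = rng.uniform(size=(n, k))
    signs[u < p_neutral] = 0.0
    signs[u > 1 - p_missing] = np.nan
    return StanceMatrix("R", pd.DataFrame(
        signs, index=[f"P{i + 1}" for i in range(n)],
        columns=[f"item{j + 1}" for j in range(k)]))


def projection_oracle_agreement(n_matrices: int = 50, n: int = 20, k: int = 8,
                                seed: int = 0, min_overlap: int = 2,
                                threshold: float = 0.4) -> int:
    """Count random stance matrices on which both vectorized projections
    exactly match the naive double-loop references (edge sets, weights,
    signs and supports)."""
    matches = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_matrices):
        s = random_stance_matrix(rng, n=n, k=k)
        fast_p = {
            tuple(sorted((u, v))): (round(w, 12), c)
            for u, v, w, _, c in project_participants(s, min_overlap, threshold).edges
        }
        naive_p = {
            tuple(sorted(k_)): (round(w, 12), c)
            for k_, (w, c) in project_participants_naive(s, min_overlap, threshold).items()
        }
        fast_a = {
            tuple(sorted((u, v))): (w, sg, c)
            for u, v, w, sg, c in project_attitudes(s).edges
        }
        naive_a = {
            tuple(sorted(k_)): (float(w), sg, c)
            for k_, (w, sg, c) in project_attitudes_naive(s).items()
        }
        matches += (fast_p == naive_p) and (fast_a == naive_a)
    return matches


def run_planted_pipeline(seed: int, config: SyntheticConfig | None = None,
                         min_overlap: int = 5, threshold: float = 0.75) -> dict:
    """Full pipeline on one synthetic cohort: generate, screen attention
    failures, match waves, project, detect components, and score recovery.

    Returns per-wave giant-component fractions, bridging-edge counts against
    the planted factions, and the wave-3 ARI of the two largest components
    against ground truth (participants outside them are excluded, matching
    the components-as-factions reading of the thresholded projection).
    """
    cfg = replace(config or SyntheticConfig(), seed=seed)
    waves, truth = generate_cohort(cfg)
    screened = []
    for w in waves:
        if any(s.block == "attention" for s in w.items):
            w, _ = apply_attention_exclusions(w, "attention_check", ATTENTION_EXPECTED)
        screened.append(w)
    matched, _ = match_waves(screened) if len(screened) > 1 else (screened, None)

    out: dict = {"n_panel": matched[0].n_participants, "waves": []}
    for wave in matched:
        stance = binarize(wave)
        graph = project_participants(stance, min_overlap, threshold)
        assignment = connected_components(graph, keep_largest=2)
        sizes = assignment.sizes()
        giant = max((v for k_, v in sizes.items() if k_ != UNASSIGNED), default=0)
        truth_labels = {p: truth.faction_of[p] for p in wave.participant_ids}
        assigned = assignment.assigned_ids()
        ari = adjusted_rand_score(
            [truth_labels[p] for p in assigned],
            [assignment.labels[p] for p in assigned],
        ) if assigned else 0.0
        out["waves"].append({
            "wave_id": wave.wave_id,
            "n_edges": graph.n_edges(),
            "giant_fraction": giant / wave.n_participants,
            "bridging_edges": bridging_edge_count(graph, truth_labels),
            "ari_top2_vs_truth": float(ari),
        })
    return out


def planted_recovery_summary(n_seeds: int = 20, seed: int = 0,
                             config: SyntheticConfig | None = None,
                             min_overlap: int = 5, threshold: float = 0.75) -> dict:
    """Aggregate :func:`run_planted_pipeline` over independent seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    runs = [run_planted_pipeline(int(s), config, min_overlap, threshold)
            for s in seeds]
    n_waves = len(runs[0]["waves"])
    bridging = np.array([[r["waves"][t]["bridging_edges"] for t in range(n_waves)]
                         for r in runs])
    return {
        "n_seeds": n_seeds,
        "ari_wave3": [r["waves"][-1]["ari_top2_vs_truth"] for r in runs],
        "giant_fraction_wave1": [r["waves"][0]["giant_fraction"] for r in runs],
        "median_bridging_by_wave": np.median(bridging, axis=0).tolist(),
    }


def eta_ci_coverage(n_reps: int = 2000, seed: int = 0, n_per_group: int = 20,
                    means: Sequence[float] = (-0.5, 0.0, 0.5), sigma: float = 1.0,
                    level: float = 0.90) -> float:
    """Empirical coverage of the eta-squared noncentral-F confidence interval.

    Simulates balanced one-way designs with known population effect
    eta^2 = Var_between / (Var_between + sigma^2) and counts how often the
    interval covers it.
    """
    rng = np.random.default_rng(seed)
    mus = np.asarray(means, dtype=float)
    centred = mus - mus.mean()
    true_eta = float(np.mean(centred ** 2) / (np.mean(centred ** 2) + sigma ** 2))
    hits = 0
    for _ in range(n_reps):
        groups = [rng.normal(mu, sigma, n_per_group) for mu in mus]
        res = oneway_anova(groups)
        lo, hi = eta_sq_ci(res.F, int(res.df1), int(res.df2), level)
        hits += lo <= true_eta <= hi
    return hits / n_reps


def logistic_recovery(seed: int = 0, n: int = 5000,
                      coefs: Sequence[float] = (0.5, -1.0)) -> dict:
    """Fit the logistic model on data with known coefficients; report the
    largest absolute estimation error in Wald-SE units."""
    rng = np.random.default_rng(seed)
    B = np.asarray(coefs, dtype=float)
    X = rng.normal(size=(n, len(B)))
    p = 1.0 / (1.0 + np.exp(-(X @ B)))
    y = (rng.uniform(size=n) < p).astype(int)
    res = logistic_fit(X, y)
    z_errors = [abs(res.params[f"x{i + 1}"] - B[i]) / res.se[f"x{i + 1}"]
                for i in range(len(B))]
    return {"max_error_in_se": float(max(z_errors)),
            "pct_correct": res.pct_correct,
            "model_chi_sq": res.model_chi_sq.statistic}
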