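"""Canonical validation experiments on synthetic embeddings.

These drivers wire the generator, sampler, probe and scores together under
the study conditions the toolkit is calibrated for: five tissue source
sites, three stage classes, a patient/slide hierarchy of 5000 tiles, unit
noise, and a controllable site batch-effect magnitude delta. They exist so
that the same experiment definitions back the test suite, the acceptance
script, and any user wanting a self-check on a new installation.
"""

from __future__ import annotations

import numpy as np

from .probe import ProbeConfig, bootstrap_metrics, evaluate_probe, train_probe
from .probe import subsample_experiment, ProbeResult
from .sampling import patient_disjoint_split
from .store import VariableSpec, subset
from .synthetic import SyntheticConfig, gen_embeddings

__all__ = [
    "site_probe_experiment",
    "delta_sweep",
    "bootstrap_coverage",
    "subsample_trend",
]

SITE = VariableSpec("site")


def site_probe_experiment(
    delta: float,
    seed: int,
    tiles_per_slide: int = 50,
    fractions: tuple[float, float, float] = (0.7, 0.0, 0.3),
    probe_config: ProbeConfig | None = None,
) -> ProbeResult:
    """Train and evaluate a site probe on one synthetic draw.

    The split is patient-disjoint and stratified by site, so the held-out
    site proportions match their population shares; without stratification
    the chance-level reference (1 / n_sites) would be biased low.
    """
    cfg = SyntheticConfig(delta=delta, sigma=1.0, seed=seed,
                          tiles_per_slide=tiles_per_slide)
    es = gen_embeddings(cfg)
    split = patient_disjoint_split(
        es, fractions=fractions, seed=seed, stratify_by="site"
    )
    train = subset(es, split.ids_in("train"))
    test = subset(es, split.ids_in("test"))
    pc = probe_config or ProbeConfig(seed=seed)
    model = train_probe(train, SITE, pc)
    return evaluate_probe(model, test, SITE, pc)


def delta_sweep(
    deltas: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    n_seeds: int = 5,
    seed: int = 0,
    tiles_per_slide: int = 50,
) -> dict[float, float]:
    """Mean site-probe accuracy per batch-effect magnitude over seeds.

    Accuracy should be non-decreasing in delta: more site signal in the
    embedding space can only make the site more linearly decodable.
    """
    out = {}
    for delta in deltas:
        accs = [
            site_probe_experiment(
                delta, seed=seed * 1000 + r, tiles_per_slide=tiles_per_slide,
                probe_config=ProbeConfig(n_bootstrap=10, seed=r),
            ).accuracy
            for r in range(n_seeds)
        ]
        out[delta] = float(np.mean(accs))
    return out


def bootstrap_coverage(
    p_correct: float = 0.7,
    n_test: int = 500,
    n_runs: int = 100,
    n_bootstrap: int = 100,
    ci_level: float = 0.95,
    seed: int = 0,
) -> int:
    """How often the bootstrap CI covers the true per-item correctness rate.

    Simulates a classifier whose predictions are independently correct with
    probability ``p_correct``, builds the percentile CI from resampled
    accuracies, and counts the runs whose interval contains ``p_correct``.
    For a well-calibrated 95% interval this is ~95 of 100.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    alpha = (1.0 - ci_level) / 2.0
    for r in range(n_runs):
        correct = rng.random(n_test) < p_correct
        y_true = np.array(["a"] * n_test, dtype=object)
        y_pred = np.where(correct, "a", "b").astype(object)
        accs, _ = bootstrap_metrics(
            y_true, y_pred, ["a", "b"], n_bootstrap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        lo = np.percentile(accs, 100 * alpha)
        hi = np.percentile(accs, 100 * (1 - alpha))
        covered += int(lo <= p_correct <= hi)
    return covered


def subsample_trend(
    delta: float = 2.0,
    n_seeds: int = 5,
    small_fraction: float = 0.05,
    seed: int = 0,
    tiles_per_slide: int = 50,
) -> int:
    """Paired seeds where full-data accuracy >= small-fraction accuracy.

    Mirrors the qualitative pattern that probe accuracy grows with training
    set size; the small-fraction run compensates with more epochs.
    """
    wins = 0
    for r in range(n_seeds):
        cfg = SyntheticConfig(delta=delta, sigma=1.0, seed=seed * 1000 + r,
                              tiles_per_slide=tiles_per_slide)
        es = gen_embeddings(cfg)
        split = patient_disjoint_split(es, fractions=(0.7, 0.0, 0.3),
                                       seed=r, stratify_by="site")
        train = subset(es, split.ids_in("train"))
        test = subset(es, split.ids_in("test"))
        table = subsample_experiment(
            train, test, SITE, [small_fraction, 1.0], repeats=1,
            config=ProbeConfig(n_bootstrap=10, seed=r),
        )
        accs = dict(zip(table.fraction, table.mean_accuracy))
        wins += int(accs[1.0] >= accs[small_fraction])
    return wins
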