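"""Training-loop integration: periodic bias inspection on validation embeddings.

The hook is deliberately model-agnostic: the host training loop extracts
validation embeddings however it likes and hands them over; the hook never
touches a model handle. Every ``every_n`` epochs it trains light-weight
linear probes for the configured variables on an internal patient-disjoint
split of the provided embeddings, optionally scores a 2-D projection, logs
a metric record, and can signal early stop when a probe accuracy crosses a
threshold (e.g. stop when site accuracy rises above 0.9 — the encoder is
learning the batch, not the biology).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

from .probe import ProbeConfig, evaluate_probe, train_probe
from .projector import ProjectorParams, project
from .sampling import patient_disjoint_split
from .scores import score_projection
from .store import EmbeddingSet, VariableSpec, subset

__all__ = ["InspectionPolicy", "MetricRecord", "on_epoch_end", "write_history",
           "read_history"]

#: lighter probe defaults for in-loop use, bounding per-checkpoint cost
IN_LOOP_PROBE = ProbeConfig(epochs=5, n_bootstrap=25)


@dataclass(frozen=True)
class InspectionPolicy:
    """What to inspect, how often, and when to stop.

    ``stop_rule`` is (variable_name, comparator, threshold) with comparator
    "above" or "below", applied to that variable's probe accuracy.
    """

    variables: tuple[VariableSpec, ...]
    every_n: int = 20
    probe_config: ProbeConfig = IN_LOOP_PROBE
    projector_params: ProjectorParams | None = None
    stop_rule: tuple[str, str, float] | None = None
    unit_var: str = "patient"
    score_variable: str | None = None

    def __post_init__(self) -> None:
        if self.every_n < 1:
            raise ValueError("every_n must be >= 1")
        if self.stop_rule is not None:
            var, comparator, threshold = self.stop_rule
            if comparator not in ("above", "below"):
                raise ValueError("stop_rule comparator must be 'above' or 'below'")
            if not 0.0 <= threshold <= 1.0:
                raise ValueError("stop_rule threshold must be in [0, 1]")
            if var not in {v.name for v in self.variables}:
                raise ValueError(f"stop_rule variable {var!r} not among variables")


@dataclass
class MetricRecord:
    epoch: int
    probes: dict[str, dict]  # variable name -> ProbeResult summary
    scores: dict | None = None
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "probes": self.probes,
            "scores": self.scores,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricRecord":
        return cls(
            epoch=d["epoch"],
            probes=d["probes"],
            scores=d.get("scores"),
            timestamp=d.get("timestamp", ""),
        )


def on_epoch_end(
    epoch: int,
    embeddings: EmbeddingSet,
    policy: InspectionPolicy,
    history: list[MetricRecord],
) -> tuple[list[MetricRecord], str]:
    """Run one inspection checkpoint; returns (new history, action).

    Off-schedule epochs return the history unchanged with action
    "continue". On-schedule epochs append a :class:`MetricRecord`; the
    action is "stop" iff the stop rule fires. ``embeddings`` and
    ``policy`` are never mutated.
    """
    if epoch < 1:
        raise ValueError("epoch must be >= 1")
    if epoch % policy.every_n != 0:
        return history, "continue"

    for v in policy.variables:
        if v.name not in embeddings.metadata.columns:
            raise KeyError(f"variable {v.name!r} missing from embeddings")

    split = patient_disjoint_split(
        embeddings,
        unit_var=policy.unit_var,
        fractions=(0.7, 0.0, 0.3),
        seed=policy.probe_config.seed,
    )
    train_set = subset(embeddings, split.ids_in("train"))
    test_set = subset(embeddings, split.ids_in("test"))

    probes: dict[str, dict] = {}
    accuracies: dict[str, float] = {}
    for v in policy.variables:
        model = train_probe(train_set, v, policy.probe_config)
        res = evaluate_probe(model, test_set, v, policy.probe_config)
        accuracies[v.name] = res.accuracy
        probes[v.name] = {
            "accuracy": res.accuracy,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "kappa_mean": res.kappa_mean,
            "n_train": res.n_train,
            "n_test": res.n_test,
        }

    scores_dict = None
    if policy.projector_params is not None:
        proj = project(embeddings, policy.projector_params)
        score_var = policy.score_variable or policy.variables[0].name
        scores = score_projection(
            embeddings, proj, VariableSpec(score_var),
            seed=policy.probe_config.seed,
        )
        scores_dict = scores.to_dict()

    record = MetricRecord(epoch=epoch, probes=probes, scores=scores_dict)
    new_history = list(history) + [record]

    action = "continue"
    if policy.stop_rule is not None:
        var, comparator, threshold = policy.stop_rule
        acc = accuracies[var]
        if (comparator == "above" and acc > threshold) or (
            comparator == "below" and acc < threshold
        ):
            action = "stop"
    return new_history, action


def write_history(history: list[MetricRecord], path: str) -> str:
    """Line-delimited JSON, one record per line (append-safe format)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in history:
            fh.write(json.dumps(rec.to_dict()) + "\n")
    return str(path)


def read_history(path: str) -> list[MetricRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(MetricRecord.from_dict(json.loads(line)))
    return records
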