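"""Session file format: trials, spikes, choices, and the neuron registry.

A session file is JSON (format_version 1) holding, per trial, the left and
right click times, the stimulus duration, the binary choice, the identifiers
of the neurons recorded on that trial, and their spike times.  Neurons carry
a region label and a response latency so that spike binning is automatic.
Different trials may list different neurons (ragged recording layout): only
the neurons recorded on a trial contribute to its likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stimulus import ClickTrain

__all__ = ["Neuron", "Trial", "SessionData", "read_session", "write_session"]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class Neuron:
    id: str
    region: str = ""
    latency: float = 0.0


@dataclass(frozen=True)
class Trial:
    train: ClickTrain
    choice: int
    neuron_ids: tuple[str, ...]
    spikes: dict[str, np.ndarray]
    session: int = 0

    def __post_init__(self):
        if self.choice not in (0, 1):
            raise ValueError("choice must be 0 (left) or 1 (right)")
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))
        object.__setattr__(
            self,
            "spikes",
            {k: np.asarray(v, dtype=float) for k, v in self.spikes.items()},
        )
        for nid in self.spikes:
            if nid not in self.neuron_ids:
                raise ValueError(f"spikes given for unlisted neuron {nid!r}")


@dataclass
class SessionData:
    neurons: list[Neuron]
    trials: list[Trial]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = {n.id for n in self.neurons}
        if len(ids) != len(self.neurons):
            raise ValueError("duplicate neuron ids in registry")
        for k, tr in enumerate(self.trials):
            for nid in tr.neuron_ids:
                if nid not in ids:
                    raise ValueError(
                        f"trials[{k}] lists neuron {nid!r} absent from the registry"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def neuron_ids(self) -> list[str]:
        return [n.id for n in self.neurons]

    def latency_of(self, neuron_id: str) -> float:
        for n in self.neurons:
            if n.id == neuron_id:
                return n.latency
        raise KeyError(neuron_id)


def _trial_to_dict(tr: Trial) -> dict:
    return {
        "left_times": tr.train.left_times.tolist(),
        "right_times": tr.train.right_times.tolist(),
        "duration": tr.train.duration,
        "choice": int(tr.choice),
        "session": int(tr.session),
        "neurons": list(tr.neuron_ids),
        "spikes": {k: v.tolist() for k, v in tr.spikes.items()},
    }


def _trial_from_dict(d: dict, k: int) -> Trial:
    for key in ("left_times", "right_times", "duration", "choice"):
        if key not in d:
            raise ValueError(f"trials[{k}]: missing required field {key!r}")
    train = ClickTrain(
        left_times=np.asarray(d["left_times"], dtype=float),
        right_times=np.asarray(d["right_times"], dtype=float),
        duration=float(d["duration"]),
    )
    return Trial(
        train=train,
        choice=int(d["choice"]),
        neuron_ids=tuple(d.get("neurons", ())),
        spikes={k2: np.asarray(v, dtype=float) for k2, v in d.get("spikes", {}).items()},
        session=int(d.get("session", 0)),
    )


def write_session(data: SessionData, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "neurons": [
            {"id": n.id, "region": n.region, "latency": n.latency} for n in data.neurons
        ],
        "trials": [_trial_to_dict(t) for t in data.trials],
        "meta": data.meta,
    }
    Path(path).write_text(json.dumps(doc))


def read_session(path: str | Path) -> SessionData:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported format_version {doc.get('format_version')!r}"
        )
    neurons = [
        Neuron(id=n["id"], region=n.get("region", ""), latency=float(n.get("latency", 0.0)))
        for n in doc.get("neurons", [])
    ]
    trials = [_trial_from_dict(d, k) for k, d in enumerate(doc.get("trials", []))]
    return SessionData(neurons=neurons, trials=trials, meta=doc.get("meta", {}))
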