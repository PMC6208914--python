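"""File formats: two-column spike-train text files (gdf-like), CSV tables
for activation functions / transfer functions / score records, and JSON
for filter parameters, LN models and run configurations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .characterize import ActivationFunction
from .lnmodel import FilterParams, LNModel, TransferFunctionEstimate
from .trains import SpikeTrain

__all__ = [
    "RunConfig",
    "read_spike_trains",
    "write_spike_trains",
    "save_filter",
    "load_filter",
    "save_ln_model",
    "load_ln_model",
    "save_activation",
    "load_activation",
    "save_transfer_function",
    "records_dataframe",
]


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    model_class: str
    variant: str
    noise: str = "none"
    weights: List[float] = field(default_factory=lambda: [0.5])
    seed: int = 0
    dt: float = 0.1
    equilibration: float = 1000.0
    out_dir: str = "."
    extra: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_class not in ("izhikevich", "amat"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.dt <= 0 or self.equilibration < 0:
            raise ValueError("invalid grid parameters")
        if not self.weights:
            raise ValueError("at least one synaptic weight is required")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_spike_trains(path) -> List[SpikeTrain]:
    """Read trains from two-column text: train_id  time_ms.

    Times must be ascending within each id; malformed or non-monotone
    lines raise with the offending line number.  Returns trains ordered by
    id, each spanning the common window [0, max time + dt).
    """
    by_id: Dict[int, list] = {}
    last: Dict[int, float] = {}
    t_max = 0.0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'id time_ms', got {s!r}")
            try:
                tid = int(parts[0])
                t = float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed line {s!r}") from None
            if tid in last and t <= last[tid]:
                raise ValueError(
                    f"{path}:{ln}: non-monotone time {t} for train {tid}")
            last[tid] = t
            by_id.setdefault(tid, []).append(t)
            t_max = max(t_max, t)
    t_stop = t_max + 0.1
    return [SpikeTrain(np.array(by_id[tid]), t_start=0.0, t_stop=t_stop)
            for tid in sorted(by_id)]


def write_spike_trains(trains: Sequence[SpikeTrain], path) -> None:
    """Write trains as two-column text (id, time in ms, 1 us precision,
    which round-trips 0.1 ms grid times losslessly)."""
    with open(path, "w") as fh:
        for tid, tr in enumerate(trains):
            for t in tr.times:
                fh.write(f"{tid} {t:.3f}\n")


def save_filter(params: FilterParams, path) -> None:
    Path(path).write_text(json.dumps({
        "gamma1": params.gamma1, "gamma2": params.gamma2,
        "f_c1": params.f_c1, "f_c2": params.f_c2, "delay": params.delay},
        indent=1))


def load_filter(path) -> FilterParams:
    d = json.loads(Path(path).read_text())
    return FilterParams(d["gamma1"], d["gamma2"], d["f_c1"], d["f_c2"],
                        d["delay"])


def save_ln_model(model: LNModel, path) -> None:
    p = model.filter
    Path(path).write_text(json.dumps({
        "filter": {"gamma1": p.gamma1, "gamma2": p.gamma2, "f_c1": p.f_c1,
                   "f_c2": p.f_c2, "delay": p.delay},
        "activation": {"a_grid": model.activation.a_grid.tolist(),
                       "r_grid": model.activation.r_grid.tolist(),
                       "metadata": model.activation.metadata},
        "metadata": model.metadata}, indent=1))


def load_ln_model(path) -> LNModel:
    d = json.loads(Path(path).read_text())
    f = d["filter"]
    act = d["activation"]
    return LNModel(
        activation=ActivationFunction(np.array(act["a_grid"]),
                                      np.array(act["r_grid"]),
                                      act.get("metadata", {})),
        filter=FilterParams(f["gamma1"], f["gamma2"], f["f_c1"], f["f_c2"],
                            f["delay"]),
        metadata=d.get("metadata", {}))


def save_activation(act: ActivationFunction, csv_path,
                    meta_path: Optional[str] = None) -> None:
    pd.DataFrame({"a0": act.a_grid, "r0": act.r_grid}).to_csv(csv_path,
                                                              index=False)
    if meta_path:
        Path(meta_path).write_text(json.dumps(act.metadata, indent=1))


def load_activation(csv_path, meta_path: Optional[str] = None
                    ) -> ActivationFunction:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text()) if meta_path else {}
    return ActivationFunction(df["a0"].to_numpy(), df["r0"].to_numpy(), meta)


def save_transfer_function(tf: TransferFunctionEstimate, path) -> None:
    pd.DataFrame({
        "f_Hz": tf.frequencies, "re_H": tf.H.real, "im_H": tf.H.imag,
        "r1": tf.r1, "r2": tf.r2, "r1_significant": tf.r1_significant,
        "r2_significant": tf.r2_significant, "r0": tf.r0,
    }).to_csv(path, index=False)


def records_dataframe(records) -> pd.DataFrame:
    """Long-format score table (model, noise, w, a0, a1, stimulus, Er, valid)."""
    return pd.DataFrame([asdict(r) for r in records])
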