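"""File formats and pipeline configuration.

Everything on disk is plain text: tidy TSV for tables, CSV + YAML sidecar
for voltage traces, Newick for trees, YAML for configuration.  Sensillum
names use ASCII tokens (Da, Db, Dg, C, E1, E2) in files; Greek display
names live in :mod:`cimexolf.panel`.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, SchemaError
from .panel import CLASSES, PANEL, SENSILLA
from .spikes import VoltageTrace
from .tuning import ResponseMatrix


def write_response_matrix(
    matrix: ResponseMatrix, path, sem_path=None
) -> None:
    """Write the mean-rate matrix as TSV (odorant, class, one column per
    sensillum); optionally write the paired SEM table."""
    df = matrix.mean.copy()
    df.insert(0, "class", matrix.classes)
    df.index.name = "odorant"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if sem_path is not None:
        sem = matrix.sem.copy()
        sem.insert(0, "class", matrix.classes)
        sem.index.name = "odorant"
        sem.to_csv(sem_path, sep="\t", float_format="%.17g")


def read_response_matrix(path, sem_path=None, n_replicates: int = 6) -> ResponseMatrix:
    """Read a response-matrix TSV, validating schema and values."""
    df = pd.read_csv(path, sep="\t", dtype={"odorant": str})
    if "odorant" not in df.columns:
        raise SchemaError("missing 'odorant' column")
    if "class" not in df.columns:
        raise SchemaError("missing 'class' column")
    dup = df["odorant"].duplicated()
    if dup.any():
        raise SchemaError(
            f"duplicate odorant rows: {sorted(df.loc[dup, 'odorant'])}"
        )
    df = df.set_index("odorant")
    sens_cols = [c for c in df.columns if c != "class"]
    missing = set(SENSILLA) - set(sens_cols)
    if missing:
        raise SchemaError(f"missing sensillum columns: {sorted(missing)}")
    mean = df[list(SENSILLA)].apply(pd.to_numeric, errors="coerce")
    mean.columns.name = "sensillum"
    if mean.isna().any().any():
        r, c = np.argwhere(mean.isna().values)[0]
        raise SchemaError(
            f"non-numeric cell at odorant {mean.index[r]!r}, "
            f"column {mean.columns[c]!r}"
        )
    if sem_path is not None:
        sem = (
            pd.read_csv(sem_path, sep="\t")
            .set_index("odorant")[list(SENSILLA)]
            .astype(float)
        )
        sem = sem.loc[mean.index]
        sem.columns.name = "sensillum"
    else:
        sem = mean * 0.0
    n = (mean * 0 + n_replicates).astype(int)
    return ResponseMatrix(mean, sem, n, df["class"])


def write_spike_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_spike_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"odorant", "sensillum", "replicate", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"spike table missing columns: {sorted(missing)}")
    return df


def write_voltage_trace(trace: VoltageTrace, path) -> None:
    """CSV of µV samples plus a YAML metadata sidecar (`<path>.meta.yaml`)."""
    path = Path(path)
    np.savetxt(path, trace.samples, fmt="%.6g", header="value_uv", comments="")
    meta = {
        "sampling_rate": float(trace.sampling_rate),
        "stimulus_onset": trace.stimulus_onset,
        "stimulus_duration": trace.stimulus_duration,
        **{
            k: v
            for k, v in trace.metadata.items()
            if isinstance(v, (str, int, float, type(None)))
        },
    }
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_voltage_trace(path) -> VoltageTrace:
    path = Path(path)
    samples = np.loadtxt(path, skiprows=1)
    meta_path = Path(f"{path}.meta.yaml")
    if not meta_path.exists():
        raise SchemaError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    try:
        fs = float(meta.pop("sampling_rate"))
    except KeyError as exc:
        raise SchemaError("sidecar missing sampling_rate") from exc
    onset = meta.pop("stimulus_onset", None)
    stim = meta.pop("stimulus_duration", 0.5)
    return VoltageTrace(
        samples, fs, stimulus_onset=onset, stimulus_duration=stim, metadata=meta
    )


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    panel: dict = field(default_factory=lambda: dict(PANEL))
    n_replicates: int = 6
    reference_dose: float = -2.0
    dose_grid: list = field(
        default_factory=lambda: [-6.0, -5.0, -4.0, -3.0, -2.0, -1.0]
    )
    stimulus_onset: float = 1.0
    stimulus_duration: float = 0.5
    recording_duration: float = 3.5
    psth_window: float = 2.0
    psth_bin: float = 0.1
    non_responder_threshold: float = 15.0
    excitatory_threshold: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.non_responder_threshold <= 0 or self.excitatory_threshold <= 0:
            raise InvalidParameterError("thresholds must be positive")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        bad = set(self.panel.values()) - set(CLASSES)
        if bad:
            raise SchemaError(f"panel classes outside the vocabulary: {bad}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError("config must be a YAML mapping")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
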