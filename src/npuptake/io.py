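"""Readers and writers for the delimited-text formats the pipeline exchanges.

Tabular inputs are plain comma- or tab-separated text (dialect auto-detected
from the header line); all structured outputs are JSON.  ΔD is exchanged in
the conventional 1e-6 units (column ``delta_d_1e6``) and stored internally
as a pure number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anisotropy import PolarizedIntensities
from .errors import SchemaError
from .inversion import QcmTrace
from .kinetics import AnchoringSample, BarrierEstimate

QCM_COLUMNS = ("time_s", "overtone", "delta_f_hz", "delta_d_1e6")
ANCHOR_COLUMNS = ("chol_pct", "trial_id", "wait_ns", "censored", "n_anchors_1us")
ANIS_COLUMNS = ("chol_pct", "i_vv", "i_vh", "i_hv", "i_hh")
BARRIER_COLUMNS = ("chol_pct", "delta_g_kj_mol")


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_qcm_table(path: str | Path) -> QcmTrace:
    """Read a long-format QCM-D export into a :class:`QcmTrace`.

    Required columns: time_s, overtone, delta_f_hz, delta_d_1e6; an optional
    ``phase`` column is carried through.  Rows with non-odd or non-positive
    overtones are rejected with their line numbers.
    """
    df = _read_table(path, QCM_COLUMNS)
    bad = df.index[(df["overtone"] <= 0) | (df["overtone"] % 2 == 0)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise SchemaError(
            f"{path}: non-odd or non-positive overtone on line(s) {rows}"
        )
    overtones = tuple(sorted(int(n) for n in df["overtone"].unique()))
    pivot_f = df.pivot_table(index="time_s", columns="overtone",
                             values="delta_f_hz", aggfunc="mean")
    pivot_d = df.pivot_table(index="time_s", columns="overtone",
                             values="delta_d_1e6", aggfunc="mean")
    if pivot_f.isna().any().any() or pivot_d.isna().any().any():
        raise SchemaError(f"{path}: overtone set differs between time points")
    phase = None
    if "phase" in df.columns:
        ph = df.drop_duplicates("time_s").set_index("time_s")["phase"]
        phase = ph.loc[pivot_f.index].to_numpy(dtype=object)
    return QcmTrace(
        time=pivot_f.index.to_numpy(dtype=float),
        overtones=overtones,
        delta_f=pivot_f[list(overtones)].to_numpy(dtype=float),
        delta_d=pivot_d[list(overtones)].to_numpy(dtype=float) * 1e-6,
        phase=phase,
    )


def write_qcm_table(trace: QcmTrace, path: str | Path) -> None:
    """Write a trace in the long delimited format ``read_qcm_table`` accepts."""
    rows = []
    for i, t in enumerate(trace.time):
        for k, n in enumerate(trace.overtones):
            row = {
                "time_s": repr(float(t)),
                "overtone": n,
                "delta_f_hz": repr(float(trace.delta_f[i, k])),
                "delta_d_1e6": repr(float(trace.delta_d[i, k] * 1e6)),
            }
            if trace.phase is not None:
                row["phase"] = trace.phase[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_anchoring_table(path: str | Path) -> dict[float, AnchoringSample]:
    """Read per-trial anchoring waits grouped by cholesterol condition.

    The run length of each condition is inferred as the maximum wait among
    its censored trials (or the overall maximum wait when none is censored).
    """
    df = _read_table(path, ANCHOR_COLUMNS)
    out: dict[float, AnchoringSample] = {}
    for chol, grp in df.groupby("chol_pct"):
        waits = grp["wait_ns"].to_numpy(dtype=float)
        censored = grp["censored"].astype(bool).to_numpy()
        run_length = float(waits[censored].max()) if censored.any() else float(waits.max())
        out[float(chol)] = AnchoringSample(
            chol_pct=float(chol), waits=waits, censored=censored,
            run_length=run_length,
            n_anchors_window=grp["n_anchors_1us"].to_numpy(dtype=float),
        )
    return out


def write_anchoring_table(samples: dict[float, AnchoringSample], path: str | Path) -> None:
    rows = []
    for chol in sorted(samples):
        s = samples[chol]
        for i in range(s.n_trials):
            rows.append({
                "chol_pct": chol,
                "trial_id": i,
                "wait_ns": repr(float(s.waits[i])),
                "censored": bool(s.censored[i]),
                "n_anchors_1us": float(s.n_anchors_window[i])
                if s.n_anchors_window is not None else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_anisotropy_table(path: str | Path) -> dict[float, list[PolarizedIntensities]]:
    df = _read_table(path, ANIS_COLUMNS)
    out: dict[float, list[PolarizedIntensities]] = {}
    for chol, grp in df.groupby("chol_pct"):
        out[float(chol)] = [
            PolarizedIntensities(r.i_vv, r.i_vh, r.i_hv, r.i_hh)
            for r in grp.itertuples()
        ]
    return out


def write_anisotropy_table(
    study: dict[float, list[PolarizedIntensities]], path: str | Path
) -> None:
    rows = []
    for chol in sorted(study):
        for p in study[chol]:
            rows.append({
                "chol_pct": chol,
                "i_vv": repr(float(p.i_vv)), "i_vh": repr(float(p.i_vh)),
                "i_hv": repr(float(p.i_hv)), "i_hh": repr(float(p.i_hh)),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_barrier_table(path: str | Path, source: str = "external_metadynamics"
                       ) -> list[BarrierEstimate]:
    df = _read_table(path, BARRIER_COLUMNS)
    return [BarrierEstimate(chol_pct=float(r.chol_pct),
                            delta_g=float(r.delta_g_kj_mol), source=source)
            for r in df.itertuples()]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def dump_json(obj, path: str | Path) -> None:
    """Serialize a (possibly dataclass/ndarray-bearing) object deterministically."""
    Path(path).write_text(dumps_json(obj))


def dumps_json(obj) -> str:
    return json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n"


def sha256_of(obj) -> str:
    """Stable content digest of a JSON-serializable object or a file path."""
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()
    return hashlib.sha256(dumps_json(obj).encode()).hexdigest()
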