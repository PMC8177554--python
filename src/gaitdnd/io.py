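"""Reading and writing two-channel VGRF gait records and tabular outputs.

A gait record holds the vertical ground reaction force (VGRF) measured
under the left and right foot, sampled at a common rate (300 Hz for the
PhysioNet neurodegenerative-gait recordings).  Two on-disk dialects are
supported:

``plain_text``
    Whitespace- or comma-separated columns ``time_s  left_force
    right_force`` with an optional header line.  This is the canonical
    interchange format of the package.
``wfdb``
    A minimal subset of the WFDB record format (``.hea`` header plus a
    format-16 little-endian ``.dat`` signal file), enough to consume the
    PhysioNet records and to round-trip records written by this module.

Subject identity and diagnostic class are carried by a *manifest* — a YAML
mapping or a CSV table from record stem to ``{subject_id, condition}`` —
because the filename conventions of public archives vary.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Diagnostic class labels, in the fixed order used everywhere downstream
#: (also the ECOC tie-break order).
CONDITIONS = ("CON", "ALS", "PD", "HD")

#: Per-channel statistical descriptors, in feature-vector order.
FEATURE_NAMES = ("rms", "var", "skew", "kurt")

#: Signal families a feature vector can describe.
SIGNAL_TYPES = ("vgrf", "stride", "stance", "swing")

#: Column layout of a feature table: metadata then the 8 descriptors,
#: channel-major (left block then right block).
FEATURE_COLUMNS = (
    "subject_id",
    "window_index",
    "condition",
    "signal_type",
    *[f"{name}_{foot}" for foot in ("left", "right") for name in FEATURE_NAMES],
)


@dataclass
class GaitRecord:
    """One subject's labeled two-channel VGRF recording."""

    subject_id: str
    condition: str
    fs_hz: float
    left: np.ndarray
    right: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim != 1 or self.right.ndim != 1:
            raise ValueError("force channels must be 1-D")
        if self.left.size != self.right.size:
            raise ValueError(
                f"left/right channel lengths differ "
                f"({self.left.size} vs {self.right.size})"
            )
        if self.left.size < 1:
            raise ValueError("record must contain at least one sample")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                f"expected one of {list(CONDITIONS)}"
            )

    @property
    def n_samples(self) -> int:
        return self.left.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds; sample k sits at k / fs."""
        return np.arange(self.n_samples) / self.fs_hz


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------

def _read_plain_text(path: Path) -> tuple[float, np.ndarray, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    tokens = re.split(r"[,\s]+", first.strip())
    try:
        [float(t) for t in tokens if t]
    except ValueError:
        skip = 1
    data = np.loadtxt(path, skiprows=skip, delimiter="," if "," in first else None)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError(
            f"{path}: expected 2 force channels "
            f"(columns time_s, left_force, right_force)"
        )
    if data.shape[1] > 3:
        raise ValueError(f"{path}: expected exactly 2 force channels, "
                         f"got {data.shape[1] - 1}")
    t = data[:, 0]
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return fs, data[:, 1], data[:, 2]


def _write_plain_text(record: GaitRecord, path: Path) -> None:
    t = record.times()
    with open(path, "w") as fh:
        fh.write("time_s\tleft_force\tright_force\n")
        for ti, li, ri in zip(t, record.left, record.right):
            fh.write(f"{ti:.17g}\t{li:.17g}\t{ri:.17g}\n")


# ---------------------------------------------------------------------------
# minimal WFDB dialect (header + format-16 signals)
# ---------------------------------------------------------------------------

def _read_wfdb(path: Path) -> tuple[float, np.ndarray, np.ndarray]:
    """Read a WFDB record pair; only format 16 (int16 LE) is supported."""
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
    n_samp = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    if n_sig != 2:
        raise ValueError(f"{hea}: expected 2 force channels, got {n_sig}")
    gains, baselines, dat_name, fmts = [], [], None, []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        dat_name = tok[0]
        fmts.append(tok[1])
        gain_spec = tok[2] if len(tok) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/.*)?", gain_spec)
        gain = float(m.group(1)) if m else 200.0
        if gain == 0:
            gain = 200.0
        baseline = int(m.group(2)) if m and m.group(2) else 0
        gains.append(gain)
        baselines.append(baseline)
    if any(f.split("+")[0] != "16" for f in fmts):
        raise ValueError(f"{hea}: only WFDB format 16 is supported, got {fmts}")
    raw = np.fromfile(path.parent / dat_name, dtype="<i2")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    if raw.size % n_sig:
        raise ValueError(f"{dat_name}: truncated signal file")
    raw = raw.reshape(-1, n_sig).astype(float)
    left = (raw[:, 0] - baselines[0]) / gains[0]
    right = (raw[:, 1] - baselines[1]) / gains[1]
    return fs, left, right


def _write_wfdb(record: GaitRecord, path: Path) -> None:
    """Write a format-16 WFDB pair; amplitudes scaled to the int16 range."""
    stem = path.with_suffix("")
    peak = max(float(np.max(np.abs(record.left))),
               float(np.max(np.abs(record.right))), 1e-12)
    gain = 32000.0 / peak
    adc = np.stack(
        [np.round(record.left * gain), np.round(record.right * gain)], axis=1
    ).astype("<i2")
    with open(stem.with_suffix(".hea"), "w") as fh:
        fh.write(f"{stem.name} 2 {record.fs_hz:g} {record.n_samples}\n")
        for label in ("left", "right"):
            fh.write(f"{stem.name}.dat 16 {gain:.6f}(0)/N 16 0 0 0 0 {label}\n")
    adc.tofile(stem.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# public record API
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    dialect: str = "plain_text",
    subject_id: str | None = None,
    condition: str | None = None,
    manifest: dict | None = None,
) -> GaitRecord:
    """Load a two-channel VGRF record.

    ``subject_id`` / ``condition`` fall back to the manifest entry for the
    file stem, then to parsing the stem itself (``<subject>_<condition>``
    or a condition prefix such as ``als3``).
    """
    path = Path(path)
    if dialect == "plain_text":
        fs, left, right = _read_plain_text(path)
    elif dialect == "wfdb":
        fs, left, right = _read_wfdb(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; "
                         f"expected 'plain_text' or 'wfdb'")
    stem = path.stem
    if manifest and stem in manifest:
        entry = manifest[stem]
        subject_id = subject_id or entry.get("subject_id", stem)
        condition = condition or entry.get("condition")
    if condition is None:
        for cand in CONDITIONS:
            if cand.lower() in stem.lower():
                condition = cand
                break
    if condition is None:
        raise ValueError(
            f"cannot determine condition for {path}; provide a manifest"
        )
    return GaitRecord(subject_id or stem, condition, fs, left, right)


def write_record(
    record: GaitRecord, path: str | Path, dialect: str = "plain_text"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "plain_text":
        _write_plain_text(record, path)
    elif dialect == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_manifest(path: str | Path) -> dict:
    """Read a record manifest (YAML mapping or CSV with a ``record`` column)."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        raw = yaml.safe_load(path.read_text())
        out = {}
        for stem, entry in raw.items():
            if isinstance(entry, str):
                entry = {"condition": entry}
            out[str(stem)] = {
                "subject_id": str(entry.get("subject_id", stem)),
                "condition": entry["condition"],
            }
        return out
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out[row["record"]] = {
                "subject_id": row.get("subject_id", row["record"]),
                "condition": row["condition"],
            }
    return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def features_to_frame(vectors) -> pd.DataFrame:
    """Assemble FeatureVector objects into the canonical 12-column table."""
    types = {v.signal_type for v in vectors}
    if len(types) > 1:
        raise ValueError(f"mixed signal types in one table: {sorted(types)}")
    rows = [
        {
            "subject_id": v.subject_id,
            "window_index": v.window_index,
            "condition": v.condition,
            "signal_type": v.signal_type,
            **dict(zip(FEATURE_COLUMNS[4:], v.values)),
        }
        for v in vectors
    ]
    frame = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return frame


def write_features(vectors, path: str | Path) -> Path:
    """Write feature vectors as CSV with a fixed, deterministic column order."""
    frame = vectors if isinstance(vectors, pd.DataFrame) else features_to_frame(vectors)
    if not frame.empty:
        types = frame["signal_type"].unique()
        if len(types) > 1:
            raise ValueError(f"mixed signal types in one table: {sorted(types)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return frame[list(FEATURE_COLUMNS)]
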