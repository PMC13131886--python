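"""Shared data model and cohort I/O.

A cohort couples per-subject ROI x time BOLD matrices with a phenotype table
(diagnosis, demographics, motion summaries, behavioral scores) and an optional
ROI -> network mapping.  Everything is plain delimited text on disk: one
numeric table per subject, one phenotype table, one mapping table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

#: Number of parcels in the Brainnetome atlas used throughout.
DEFAULT_N_REGIONS = 246

#: Shortest series the temporal-convolution model accepts.
MIN_TIMEPOINTS = 16

PHENOTYPE_COLUMNS = (
    "subject_id",
    "diagnosis",
    "age_years",
    "sex",
    "site",
    "mean_fd_mm",
    "pct_volumes_repaired",
)


@dataclass
class RoiTimeSeries:
    """One subject's region x time signal matrix.

    ``data`` is regions x timepoints in arbitrary BOLD units; ``tr_seconds``
    is the sampling interval.  ``region_ids`` fixes the row order and is
    authoritative at the cohort level.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    region_ids: Sequence[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: data must be 2-D (regions x time)")
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError(
                f"{self.subject_id}: {len(self.region_ids)} region ids for "
                f"{self.data.shape[0]} rows"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def has_nan(self) -> bool:
        return bool(np.isnan(self.data).any())

    def copy_with(self, data: np.ndarray, provenance: str = "") -> "RoiTimeSeries":
        prov = self.provenance + ("|" if self.provenance and provenance else "") + provenance
        return RoiTimeSeries(self.subject_id, data, self.tr_seconds,
                             list(self.region_ids), prov)


@dataclass
class SubjectRecord:
    """Phenotype row: diagnosis label, demographics, motion and behavior."""

    subject_id: str
    diagnosis: int
    age_years: float
    sex: str
    site: str
    mean_fd_mm: float
    pct_volumes_repaired: float
    behavior: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in (0, 1):
            raise ValueError(f"{self.subject_id}: diagnosis must be 0 or 1")


@dataclass
class Cohort:
    """Paired time series and phenotype records sharing one acquisition grid."""

    subjects: list[tuple[RoiTimeSeries, SubjectRecord]]
    roi_network_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [ts.subject_id for ts, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")
        for ts, rec in self.subjects:
            if ts.subject_id != rec.subject_id:
                raise ValueError(f"series/record mismatch: {ts.subject_id} vs {rec.subject_id}")
        if self.subjects:
            r0 = self.subjects[0][0]
            for ts, _ in self.subjects[1:]:
                if list(ts.region_ids) != list(r0.region_ids):
                    raise ValueError(f"{ts.subject_id}: region order differs from cohort")
                if ts.tr_seconds != r0.tr_seconds:
                    raise ValueError(f"{ts.subject_id}: tr_seconds differs from cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def series(self) -> list[RoiTimeSeries]:
        return [ts for ts, _ in self.subjects]

    @property
    def records(self) -> list[SubjectRecord]:
        return [rec for _, rec in self.subjects]

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts, _ in self.subjects]

    @property
    def labels(self) -> np.ndarray:
        return np.array([rec.diagnosis for _, rec in self.subjects], dtype=int)

    @property
    def region_ids(self) -> list[str]:
        return list(self.subjects[0][0].region_ids) if self.subjects else []

    @property
    def tr_seconds(self) -> float:
        if not self.subjects:
            raise ValueError("empty cohort has no tr")
        return self.subjects[0][0].tr_seconds

    @property
    def site_levels(self) -> list[str]:
        return sorted({rec.site for _, rec in self.subjects})

    @property
    def sex_levels(self) -> list[str]:
        return sorted({rec.sex for _, rec in self.subjects})

    def subset(self, keep_ids: Sequence[str]) -> "Cohort":
        keep = set(keep_ids)
        return Cohort([p for p in self.subjects if p[0].subject_id in keep],
                      self.roi_network_map)


@dataclass
class CohortFormat:
    """How per-subject matrices are laid out on disk.

    ``orientation`` is "region_major" (rows = regions), "time_major"
    (rows = timepoints) or None to infer from the expected region count;
    square matrices cannot be inferred and require an explicit value.
    """

    tr_seconds: float
    orientation: str | None = "region_major"
    delimiter: str = "\t"
    n_regions: int = DEFAULT_N_REGIONS
    region_list_file: str | None = None


def _read_matrix(path: Path, fmt: CohortFormat) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=fmt.delimiter, ndmin=2)
    orient = fmt.orientation
    if orient is None:
        if arr.shape[0] == arr.shape[1]:
            raise ValueError(
                f"{path.name}: square matrix is orientation-ambiguous; "
                "set CohortFormat.orientation explicitly"
            )
        orient = "region_major" if arr.shape[0] == fmt.n_regions else "time_major"
    if orient == "time_major":
        arr = arr.T
    elif orient != "region_major":
        raise ValueError(f"unknown orientation {orient!r}")
    return arr


def _record_from_row(row: pd.Series) -> SubjectRecord:
    behavior = {}
    for col, val in row.items():
        if col in PHENOTYPE_COLUMNS:
            continue
        fval = float(val) if pd.notna(val) else float("nan")
        behavior[str(col)] = fval
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        diagnosis=int(row["diagnosis"]),
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        site=str(row["site"]),
        mean_fd_mm=float(row["mean_fd_mm"]),
        pct_volumes_repaired=float(row["pct_volumes_repaired"]),
        behavior=behavior,
    )


def load_cohort(
    timeseries_dir: str | Path,
    phenotype_table: str | Path,
    fmt: CohortFormat,
    roi_network_map: str | Path | None = None,
) -> Cohort:
    """Load a cohort from a directory of per-subject tables plus phenotypes.

    Subject files are matched to phenotype rows by stem == subject_id.
    Orphans on either side raise with the offending ids listed.
    """
    ts_dir = Path(timeseries_dir)
    pheno = pd.read_csv(phenotype_table, sep=None, engine="python")
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")

    files = {p.stem: p for p in sorted(ts_dir.iterdir())
             if p.suffix.lower() in (".tsv", ".csv", ".txt")}
    pheno_ids = [str(s) for s in pheno["subject_id"]]
    orphan_files = sorted(set(files) - set(pheno_ids))
    orphan_rows = sorted(set(pheno_ids) - set(files))
    if orphan_files or orphan_rows:
        raise ValueError(
            "subject file / phenotype row mismatch; "
            f"files without rows: {orphan_files}; rows without files: {orphan_rows}"
        )

    if fmt.region_list_file:
        region_ids = [ln.strip() for ln in Path(fmt.region_list_file).read_text().splitlines()
                      if ln.strip()]
    else:
        region_ids = [f"ROI{i + 1:03d}" for i in range(fmt.n_regions)]

    subjects = []
    ref_shape: tuple[int, int] | None = None
    for sid in pheno_ids:
        mat = _read_matrix(files[sid], fmt)
        if mat.shape[0] != len(region_ids):
            raise ValueError(
                f"{sid}: {mat.shape[0]} regions, expected {len(region_ids)}")
        if ref_shape is None:
            ref_shape = mat.shape
        row = pheno.loc[pheno["subject_id"].astype(str) == sid].iloc[0]
        ts = RoiTimeSeries(sid, mat, fmt.tr_seconds, region_ids)
        subjects.append((ts, _record_from_row(row)))

    net_map = None
    if roi_network_map is not None:
        net_map = pd.read_csv(roi_network_map, sep=None, engine="python")
    return Cohort(subjects, net_map)


# ---------------------------------------------------------------------------
# Generic result serialization: open tabular/structured text plus a manifest.

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _to_frames(bundle: Any) -> dict[str, Any]:
    """Flatten a result object into {name: DataFrame | json-able dict}."""
    if bundle is None:
        return {}
    if isinstance(bundle, pd.DataFrame):
        return {"table": bundle}
    if isinstance(bundle, Mapping):
        out: dict[str, Any] = {}
        scalars: dict[str, Any] = {}
        for key, val in bundle.items():
            if isinstance(val, (pd.DataFrame, np.ndarray)) or \
                    hasattr(val, "to_frames") or hasattr(val, "__dataclass_fields__") or \
                    isinstance(val, Mapping):
                for sub, frame in _to_frames(val).items():
                    out[f"{key}" if sub == "table" else f"{key}_{sub}"] = frame
            else:
                scalars[key] = val
        if scalars:
            # scalar leaves live together in one structured-text file
            out["values" if out else "table"] = scalars
        return out
    if isinstance(bundle, np.ndarray):
        if bundle.ndim == 1:
            return {"table": pd.DataFrame({"value": bundle})}
        return {"table": pd.DataFrame(bundle)}
    if hasattr(bundle, "to_frames"):
        return bundle.to_frames()
    if hasattr(bundle, "__dataclass_fields__"):
        out = {}
        for name in bundle.__dataclass_fields__:
            val = getattr(bundle, name)
            if isinstance(val, (np.ndarray, pd.DataFrame)):
                out.update({f"{name}": f for _, f in _to_frames(val).items()})
            else:
                out.setdefault("_scalars", {})[name] = val
        scalars = out.pop("_scalars", None)
        if scalars:
            out["meta"] = {k: v for k, v in scalars.items()
                           if isinstance(v, (int, float, str, bool, list, tuple))}
        return out
    raise TypeError(f"cannot serialize {type(bundle).__name__}")


def save_results(bundle: Any, out_dir: str | Path, prefix: str = "") -> pd.DataFrame:
    """Serialize a result object to TSV/JSON files and return a manifest.

    The manifest lists every written file with its sha256; an empty bundle
    yields a manifest with zero entries.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, frame in _to_frames(bundle).items():
        fname = f"{prefix}{name}"
        if isinstance(frame, pd.DataFrame):
            path = out / f"{fname}.tsv"
            frame.to_csv(path, sep="\t", index=False)
        else:
            path = out / f"{fname}.json"
            path.write_text(json.dumps(frame, indent=2, default=str) + "\n")
        rows.append({"file": path.name, "sha256": _sha256(path)})
    manifest = pd.DataFrame(rows, columns=["file", "sha256"])
    manifest.to_csv(out / f"{prefix}manifest.tsv", sep="\t", index=False)
    return manifest


def load_results(out_dir: str | Path, prefix: str = "") -> dict[str, Any]:
    """Reload everything ``save_results`` wrote, keyed by file stem."""
    out = Path(out_dir)
    loaded: dict[str, Any] = {}
    manifest = pd.read_csv(out / f"{prefix}manifest.tsv", sep="\t")
    for fname in manifest["file"] if len(manifest) else []:
        path = out / fname
        stem = path.stem[len(prefix):] if prefix and path.stem.startswith(prefix) else path.stem
        if path.suffix == ".tsv":
            loaded[stem] = pd.read_csv(path, sep="\t")
        else:
            loaded[stem] = json.loads(path.read_text())
    return loaded
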