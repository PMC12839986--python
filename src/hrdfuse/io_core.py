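"""On-disk formats, patient-disjoint splitting, preprocessing, leakage guards.

Formats (all text UTF-8, LF endings, except the bag store):

* expression: TSV, genes as rows, first column ``gene_id``, header row of
  sample IDs;
* clinical: CSV with required columns ``patient_id, ge_burden,
  aneuploidy_score, histology, sig_hrd_1..3`` plus any number of ``timex_*``
  columns (treated as opaque numerics);
* labels: CSV ``patient_id,hrd_label`` with values HRD_HIGH / HRD_LOW;
* splits: JSON manifest;
* embedding bags: one HDF5 file holding one ``n_patches x d`` dataset per
  patient, with a JSON sidecar manifest (chosen for partial reads).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIN, VALIDATION, TEST = "train", "validation", "test"
SPLITS = (TRAIN, VALIDATION, TEST)

REQUIRED_CLINICAL = (
    "patient_id",
    "ge_burden",
    "aneuploidy_score",
    "histology",
    "sig_hrd_1",
    "sig_hrd_2",
    "sig_hrd_3",
)


class ParseError(ValueError):
    """Malformed on-disk artifact; message carries the offending line number."""


class LeakageError(RuntimeError):
    """A patient appears in more than one data split."""


class StateError(RuntimeError):
    """Preprocessing applied before fitting, or fit on non-training rows."""


# ---------------------------------------------------------------------------
# Split manifests
# ---------------------------------------------------------------------------


@dataclass
class SplitManifest:
    """Patient-disjoint train/validation/test assignment."""

    assignments: dict[str, str]
    stratify_on: str
    seed: int
    class_proportions: dict[str, dict[str, float]] = field(default_factory=dict)

    def split(self, name: str) -> list[str]:
        return [p for p, s in self.assignments.items() if s == name]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": self.assignments,
            "stratify_on": self.stratify_on,
            "seed": self.seed,
            "class_proportions": self.class_proportions,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            assignments=payload["assignments"],
            stratify_on=payload["stratify_on"],
            seed=payload["seed"],
            class_proportions=payload.get("class_proportions", {}),
        )


def _largest_remainder(count: int, fractions: list[float]) -> list[int]:
    """Apportion ``count`` items across fractions, largest remainder first."""
    quotas = [count * f for f in fractions]
    floors = [int(np.floor(q)) for q in quotas]
    short = count - sum(floors)
    order = np.argsort([-(q - fl) for q, fl in zip(quotas, floors)], kind="stable")
    for j in order[:short]:
        floors[j] += 1
    return floors


def make_splits(
    patients: list[tuple[str, str]],
    fractions: tuple[float, float],
    seed: int,
    stratify_on: str = "hrd_label",
) -> SplitManifest:
    """Stratified patient-disjoint splitting with largest-remainder rounding.

    ``fractions`` = (train, validation); the remainder forms the test split.
    Within each label class the class count is apportioned across the three
    splits by largest-remainder rounding, so split prevalences track the
    global prevalence as closely as integer counts allow.  Deterministic
    under ``seed``.
    """
    f_train, f_val = fractions
    if f_train <= 0 or f_val < 0 or f_train + f_val >= 1.0:
        raise ValueError(
            "fractions must be positive with train + validation < 1 "
            f"(got {fractions!r})"
        )
    ids = [p for p, _ in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    by_class: dict[str, list[str]] = {}
    for pid, label in patients:
        by_class.setdefault(label, []).append(pid)

    n_splits_used = 2 if f_val == 0 else 3
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    for label in sorted(by_class):
        members = sorted(by_class[label])
        if len(members) < n_splits_used:
            raise ValueError(
                f"class {label!r} has {len(members)} patients, fewer than the "
                f"{n_splits_used} splits requested"
            )
        rng.shuffle(members)
        n_tr, n_va, n_te = _largest_remainder(
            len(members), [f_train, f_val, 1.0 - f_train - f_val]
        )
        for pid in members[:n_tr]:
            assignments[pid] = TRAIN
        for pid in members[n_tr : n_tr + n_va]:
            assignments[pid] = VALIDATION
        for pid in members[n_tr + n_va :]:
            assignments[pid] = TEST

    label_of = dict(patients)
    proportions: dict[str, dict[str, float]] = {}
    for s in SPLITS:
        in_split = [label_of[p] for p, sp in assignments.items() if sp == s]
        if in_split:
            proportions[s] = {
                lab: in_split.count(lab) / len(in_split) for lab in sorted(by_class)
            }
    return SplitManifest(
        assignments=assignments,
        stratify_on=stratify_on,
        seed=seed,
        class_proportions=proportions,
    )


@dataclass
class LeakageReport:
    passed: bool
    offenders: list[str]

    def raise_if_failed(self) -> None:
        if not self.passed:
            raise LeakageError(
                f"patient(s) assigned to multiple splits: {sorted(self.offenders)}"
            )


def assert_no_leakage(*manifests: SplitManifest) -> LeakageReport:
    """Check that train/validation/test patient sets are pairwise disjoint.

    Accepts one or more manifests; pooled split membership across all
    manifests must keep every patient in a single split.
    """
    membership: dict[str, set[str]] = {}
    for m in manifests:
        for pid, split in m.assignments.items():
            membership.setdefault(pid, set()).add(split)
    offenders = sorted(p for p, splits in membership.items() if len(splits) > 1)
    report = LeakageReport(passed=not offenders, offenders=offenders)
    if offenders:
        logger.error("leakage detected: %s", offenders)
    return report


# ---------------------------------------------------------------------------
# Preprocessing (fit on training split only)
# ---------------------------------------------------------------------------


@dataclass
class PreprocessState:
    numeric_means: dict[str, float]
    numeric_sds: dict[str, float]
    categorical_levels: dict[str, list[str]]
    constant_features: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)


def fit_preprocess(
    rows: pd.DataFrame,
    manifest: SplitManifest | None = None,
    id_column: str = "patient_id",
) -> PreprocessState:
    """Fit z-scoring (population-sd convention) and one-hot level sets.

    When a manifest is given, every row must belong to its training split;
    any other row raises :class:`StateError` -- statistics must never see
    validation or test patients.
    """
    if manifest is not None:
        train_ids = set(manifest.split(TRAIN))
        outside = [pid for pid in rows[id_column] if pid not in train_ids]
        if outside:
            raise StateError(
                f"fit_preprocess received non-training rows: {sorted(outside)[:5]}"
            )
    numeric_means: dict[str, float] = {}
    numeric_sds: dict[str, float] = {}
    categorical_levels: dict[str, list[str]] = {}
    constant: list[str] = []
    names: list[str] = []
    for col in rows.columns:
        if col == id_column:
            continue
        if pd.api.types.is_numeric_dtype(rows[col]):
            mu = float(rows[col].mean())
            sd = float(rows[col].std(ddof=0))
            numeric_means[col] = mu
            if sd > 0:
                numeric_sds[col] = sd
            else:
                numeric_sds[col] = 1.0
                constant.append(col)
                logger.warning("feature %r constant on the training split", col)
            names.append(col)
        else:
            levels = sorted(rows[col].astype(str).unique())
            categorical_levels[col] = levels
            names.extend(f"{col}={lev}" for lev in levels)
    return PreprocessState(
        numeric_means=numeric_means,
        numeric_sds=numeric_sds,
        categorical_levels=categorical_levels,
        constant_features=constant,
        feature_names=names,
    )


def apply_preprocess(
    state: PreprocessState, rows: pd.DataFrame, id_column: str = "patient_id"
) -> np.ndarray:
    """Transform rows into a numeric matrix using training-split statistics.

    Categorical levels unseen at fit time map to an all-zeros one-hot block
    (level sets are frozen on the training split) with a logged warning.
    """
    if not isinstance(state, PreprocessState):
        raise StateError("apply_preprocess called before fit_preprocess")
    cols: list[np.ndarray] = []
    for col in state.numeric_means:
        z = (rows[col].to_numpy(float) - state.numeric_means[col]) / state.numeric_sds[col]
        cols.append(z)
    for col, levels in state.categorical_levels.items():
        values = rows[col].astype(str).to_numpy()
        unseen = sorted(set(values) - set(levels))
        if unseen:
            warnings.warn(
                f"unseen level(s) {unseen} in feature {col!r}; encoding as zeros",
                RuntimeWarning,
                stacklevel=2,
            )
            logger.warning("unseen levels %s in %r", unseen, col)
        for lev in levels:
            cols.append((values == lev).astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def _check_rectangular(path: Path, sep: str) -> None:
    with open(path, encoding="utf-8") as fh:
        width = None
        for lineno, line in enumerate(fh, start=1):
            ncols = line.rstrip("\n").count(sep) + 1
            if width is None:
                width = ncols
            elif ncols != width:
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({ncols} fields, expected {width})"
                )


def write_expression_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a genes x samples matrix; index = gene ids, columns = sample ids."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path, "\t")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id' (line 1)")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        for lineno, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ParseError(f"{path}: non-numeric cell at line {lineno}")
    return df


def write_labels_csv(path: str | Path, labels: pd.DataFrame | dict[str, str]) -> None:
    if isinstance(labels, dict):
        labels = pd.DataFrame(
            {"patient_id": list(labels), "hrd_label": list(labels.values())}
        )
    labels.to_csv(path, index=False, lineterminator="\n")


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path, ",")
    df = pd.read_csv(path)
    if list(df.columns) != ["patient_id", "hrd_label"]:
        raise ParseError(f"{path}: header must be patient_id,hrd_label (line 1)")
    return df


def write_clinical_csv(path: str | Path, clinical: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CLINICAL if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns {missing}")
    clinical.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path, ",")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing} (line 1)")
    return df


# ---------------------------------------------------------------------------
# Embedding-bag store
# ---------------------------------------------------------------------------


def write_bag_store(
    path: str | Path, bags: dict[str, np.ndarray], encoder_name: str = "unknown"
) -> None:
    """Write one n_patches x d matrix per patient into a single HDF5 file.

    Empty bags are rejected (a slide must yield at least one patch).  A JSON
    sidecar ``<path>.manifest.json`` records patients, shapes and encoder.
    """
    path = Path(path)
    records = {}
    for pid, bag in bags.items():
        arr = np.asarray(bag, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError(f"bag for patient {pid!r} must be a nonempty 2-D matrix")
        if not np.isfinite(arr).all():
            raise ValueError(f"bag for patient {pid!r} contains non-finite entries")
        records[pid] = arr
    with h5py.File(path, "w") as fh:
        fh.attrs["encoder_name"] = encoder_name
        for pid, arr in records.items():
            fh.create_dataset(pid, data=arr)
    manifest = {
        "encoder_name": encoder_name,
        "patients": {pid: list(arr.shape) for pid, arr in records.items()},
    }
    Path(str(path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )


def read_bag_store(
    path: str | Path, patient_ids: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Read bags back; ``patient_ids`` enables partial reads of large stores."""
    with h5py.File(path, "r") as fh:
        ids = patient_ids if patient_ids is not None else sorted(fh.keys())
        return {pid: np.asarray(fh[pid]) for pid in ids}


# ---------------------------------------------------------------------------
# Cohort manifests and complete-case filtering
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Paths of a cohort's on-disk artifacts under one root directory."""

    root: Path
    expression: str = "expression.tsv"
    inferred_expression: str = "inferred_expression.tsv"
    clinical: str = "clinical.csv"
    labels: str = "labels.csv"
    bags: str = "bags.h5"
    version: str = "1"

    def path(self, name: str) -> Path:
        return Path(self.root) / getattr(self, name)


def write_cohort(root: str | Path, patients, truth=None) -> CohortManifest:
    """Serialize a synthetic cohort (list of SyntheticPatient) to disk."""
    from . import synthdata

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest(root=root)
    genes = synthdata.gene_names(len(patients[0].true_expression))
    ids = [p.patient_id for p in patients]
    expr = pd.DataFrame(
        np.column_stack([p.true_expression for p in patients]), index=genes, columns=ids
    )
    inferred = pd.DataFrame(
        np.column_stack([p.inferred_expression for p in patients]),
        index=genes,
        columns=ids,
    )
    write_expression_tsv(manifest.path("expression"), expr)
    write_expression_tsv(manifest.path("inferred_expression"), inferred)
    clin_rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "ge_burden": p.clinical.ge_burden,
            "aneuploidy_score": p.clinical.aneuploidy_score,
            "histology": p.clinical.histology,
        }
        for j, v in enumerate(p.clinical.sig_hrd, start=1):
            row[f"sig_hrd_{j}"] = v
        for j, v in enumerate(p.clinical.timex, start=1):
            row[f"timex_{j}"] = v
        clin_rows.append(row)
    write_clinical_csv(manifest.path("clinical"), pd.DataFrame(clin_rows))
    write_labels_csv(
        manifest.path("labels"), {p.patient_id: p.hrd_label for p in patients}
    )
    write_bag_store(
        manifest.path("bags"), {p.patient_id: p.bag for p in patients}, "synthetic"
    )
    if truth is not None:
        payload = {
            "de_gene_ids": truth.de_gene_ids,
            "synergy_pairs": [list(p) for p in truth.synergy_pairs],
            "hrd_logit_weights": list(map(float, truth.hrd_logit_weights)),
        }
        (root / "planted_truth.json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )
    return manifest


def filter_complete_cases(manifest: CohortManifest) -> list[str]:
    """Retain patients with a bag, an expression column and full clinical data.

    Order follows the clinical table; an empty result is allowed (logged).
    """
    clinical = read_clinical_csv(manifest.path("clinical"))
    expr_cols = set(read_expression_tsv(manifest.path("expression")).columns)
    bag_path = manifest.path("bags")
    if bag_path.exists():
        with h5py.File(bag_path, "r") as fh:
            bag_ids = set(fh.keys())
    else:
        bag_ids = set()
    retained = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        if pid not in expr_cols or pid not in bag_ids:
            continue
        if row.isna().any():
            continue
        retained.append(pid)
    if not retained:
        logger.warning("complete-case filtering retained no patients")
    return retained
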