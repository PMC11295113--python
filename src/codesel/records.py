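"""Long-format code records -> aggregated, ancestor-closed binary matrices.

Raw administrative extracts are streams of ``(patient_id, event_date,
code, system)`` rows.  For each patient, all codes falling in the same
fixed-width window following that patient's first event are pooled into
one record; the pooled code sets are then one-hot encoded together with
every ancestor of every observed code (ancestor closure), giving a sparse
binary record x feature matrix.  Splitting is at the patient level so no
patient contributes rows to both partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .hierarchy import CodeHierarchy, CodeSystem


@dataclass
class RecordMatrix:
    """Binary record x feature matrix with patient/window metadata.

    ``values[i, j] == 1`` iff record ``i`` carries feature code
    ``feature_codes[j]``; whenever a code is set, so is every ancestor of
    that code present in ``feature_codes`` (ancestor closure).
    """

    values: np.ndarray                       # (n_records, n_features) uint8
    feature_codes: list[str]
    record_meta: pd.DataFrame                # columns: patient_id, window_index
    outcome: np.ndarray | None = None        # optional (n_records,) binary

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_codes):
            raise ValueError("values shape does not match feature_codes")
        if len(self.record_meta) != self.values.shape[0]:
            raise ValueError("record_meta length does not match values")
        if len(set(self.feature_codes)) != len(self.feature_codes):
            raise ValueError("feature_codes must be unique")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_of(self, code: str) -> int:
        return self.feature_codes.index(code)

    def take_rows(self, idx: np.ndarray) -> "RecordMatrix":
        return RecordMatrix(
            values=self.values[idx],
            feature_codes=list(self.feature_codes),
            record_meta=self.record_meta.iloc[idx].reset_index(drop=True),
            outcome=None if self.outcome is None else self.outcome[idx],
        )

    def with_outcome(self, outcome: np.ndarray) -> "RecordMatrix":
        outcome = np.asarray(outcome)
        if outcome.shape != (self.n_records,):
            raise ValueError("outcome length does not match record count")
        return replace(self, outcome=outcome)

    def check_closure(self, hierarchy: CodeHierarchy) -> bool:
        """True iff ancestor closure holds for every row."""
        col = {c: j for j, c in enumerate(self.feature_codes)}
        for j, code in enumerate(self.feature_codes):
            if code not in hierarchy:
                continue
            for anc in hierarchy.ancestors(code):
                if anc in col:
                    bad = self.values[:, j] > self.values[:, col[anc]]
                    if bad.any():
                        return False
        return True


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a long-format records file ``patient_id,date,code,system``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    required = {"patient_id", "date", "code"}
    if not required <= set(df.columns):
        raise ValueError(f"records file needs columns {sorted(required)}")
    if "system" not in df.columns:
        df["system"] = CodeSystem.SYNTH.value
    return df


def aggregate_records(records: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Pool each patient's codes into consecutive fixed-width windows.

    Windows are half-open intervals ``[first + k*window_days,
    first + (k+1)*window_days)`` anchored at the patient's own first
    event; each non-empty window yields one row whose ``codes`` column is
    the set of codes observed in it.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    dates = pd.to_datetime(records["date"], format="mixed", errors="coerce")
    if dates.isna().any():
        bad = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise ValueError(f"unparseable date at row {bad}: {records['date'].iloc[bad]!r}")
    df = records.assign(_date=dates)
    first = df.groupby("patient_id")["_date"].transform("min")
    df["window_index"] = ((df["_date"] - first).dt.days // window_days).astype(int)
    agg = (
        df.groupby(["patient_id", "window_index"])["code"]
        .agg(lambda s: frozenset(s))
        .rename("codes")
        .reset_index()
        .sort_values(["patient_id", "window_index"], kind="stable")
        .reset_index(drop=True)
    )
    return agg


def encode_one_hot(
    aggregated: pd.DataFrame,
    hierarchy: CodeHierarchy,
    system: CodeSystem = CodeSystem.SYNTH,
) -> RecordMatrix:
    """One-hot encode pooled code sets plus all their ancestors.

    Columns are the union of observed codes and every ancestor, sorted by
    code string for a deterministic order; codes absent from the
    hierarchy are resolved through its fallback rules.
    """
    closed_rows: list[set[str]] = []
    feature_set: set[str] = set()
    for codes in aggregated["codes"]:
        closed: set[str] = set()
        for code in codes:
            code = str(code)
            hierarchy.resolve(code, system)
            closed.add(code)
            closed.update(hierarchy.ancestors(code))
        closed_rows.append(closed)
        feature_set |= closed

    feature_codes = sorted(feature_set)
    col = {c: j for j, c in enumerate(feature_codes)}
    values = np.zeros((len(closed_rows), len(feature_codes)), dtype=np.uint8)
    for i, closed in enumerate(closed_rows):
        values[i, [col[c] for c in closed]] = 1

    meta = aggregated[["patient_id", "window_index"]].reset_index(drop=True)
    return RecordMatrix(values=values, feature_codes=feature_codes, record_meta=meta)


def split_by_patient(
    matrix: RecordMatrix, train_fraction: float, seed: int
) -> tuple[RecordMatrix, RecordMatrix]:
    """Patient-level train/test split via a seeded shuffle of patient IDs.

    Every patient's rows land wholly in one partition; the train share of
    patients is ``round(train_fraction * n_patients)`` clamped so both
    partitions are non-empty.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    patients = np.array(sorted(matrix.record_meta["patient_id"].unique()))
    if len(patients) < 2:
        raise ValueError("need at least 2 distinct patients to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = set(patients[:n_train])
    mask = matrix.record_meta["patient_id"].isin(train_ids).to_numpy()
    return matrix.take_rows(np.flatnonzero(mask)), matrix.take_rows(np.flatnonzero(~mask))


def save_matrix(matrix: RecordMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` + sidecar feature list and row metadata CSV."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(matrix.values))
    prefix.with_suffix(".features.txt").write_text("\n".join(matrix.feature_codes) + "\n")
    meta = matrix.record_meta.copy()
    if matrix.outcome is not None:
        meta["outcome"] = matrix.outcome
    meta.to_csv(prefix.with_suffix(".meta.csv"), index=False)


def load_matrix(prefix: str | Path) -> RecordMatrix:
    prefix = Path(prefix)
    values = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense(), dtype=np.uint8)
    codes = prefix.with_suffix(".features.txt").read_text().split()
    meta = pd.read_csv(prefix.with_suffix(".meta.csv"), dtype={"patient_id": str})
    outcome = meta.pop("outcome").to_numpy() if "outcome" in meta.columns else None
    return RecordMatrix(values=values, feature_codes=codes, record_meta=meta, outcome=outcome)
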