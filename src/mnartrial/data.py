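"""Trial data model, delimited-text IO, standardization and descriptive tables.

The data model covers a two-arm multicentre randomized trial with a continuous
quality-of-life outcome measured at baseline (``y0``) and follow-up (``y1``),
an optional carer-reported proxy score (``z``), and optional per-participant
records of the repeated attempts made to obtain the follow-up interview.

Missingness indicators (``r0``, ``r1``, ``rz``) are always *derived* from the
presence of a value, never trusted from a file, so the invariant
"indicator = 1 iff the score is present" holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttemptRecord",
    "TrialRecord",
    "TrialDataset",
    "Standardizer",
    "PatternTable",
    "read_trial_table",
    "write_trial_table",
    "standardize",
    "missingness_pattern",
    "attempts_summary",
    "ValidationError",
    "ParseError",
]

PARTICIPANT_COLUMNS = ["participant_id", "centre", "arm", "y0", "y1", "z"]
ATTEMPT_COLUMNS = ["participant_id", "m", "attempt_type", "success"]

N_CENTRES = 4
MAX_ATTEMPTS = 9

PATTERN_LABELS = ["baseline_only", "final_only", "neither", "both"]
ATTEMPT_BANDS = ["1", "2", "3", ">3"]


class ValidationError(ValueError):
    """An invariant of the trial data model is violated."""


class ParseError(ValueError):
    """A delimited-text table could not be parsed into the trial schema."""


@dataclass(frozen=True)
class AttemptRecord:
    """One attempt to obtain the follow-up interview.

    ``m`` is the 1-based attempt index (at most 9 attempts were made in the
    motivating trial), ``attempt_type`` flags whether there was a verbal
    agreement to interview, and ``success`` records whether this attempt
    yielded the interview.
    """

    m: int
    attempt_type: int
    success: int


@dataclass
class TrialRecord:
    """One participant: centre, arm, scores (possibly missing) and attempts."""

    participant_id: str
    centre: int
    arm: int
    y0: float | None = None
    y1: float | None = None
    z: float | None = None
    attempts: list[AttemptRecord] = field(default_factory=list)

    @property
    def r0(self) -> int:
        return int(self.y0 is not None and not np.isnan(self.y0))

    @property
    def r1(self) -> int:
        return int(self.y1 is not None and not np.isnan(self.y1))

    @property
    def rz(self) -> int:
        return int(self.z is not None and not np.isnan(self.z))


def _validate_attempt_sequence(ms: np.ndarray, successes: np.ndarray, pid: str) -> None:
    order = np.argsort(ms)
    ms, successes = ms[order], successes[order]
    if not np.array_equal(ms, np.arange(1, len(ms) + 1)):
        raise ValidationError(
            f"participant {pid!r}: attempt indices must be consecutive from 1, got {ms.tolist()}"
        )
    if successes.sum() > 1:
        raise ValidationError(f"participant {pid!r}: more than one successful attempt")
    if successes.sum() == 1 and successes[-1] != 1:
        raise ValidationError(
            f"participant {pid!r}: an attempt follows a successful attempt"
        )


class TrialDataset:
    """Participant table plus an optional long-format attempts table.

    Parameters
    ----------
    participants
        DataFrame with columns ``participant_id, centre, arm, y0, y1, z``
        (``z`` optional; missing scores as NaN). Centres are coded 1..4,
        arm is 0/1 (1 = intervention).
    attempts
        Optional long-format DataFrame with columns
        ``participant_id, m, attempt_type, success`` (one row per attempt).
    """

    def __init__(
        self,
        participants: pd.DataFrame,
        attempts: pd.DataFrame | None = None,
        validate: bool = True,
    ):
        df = participants.copy()
        for col in ("y0", "y1", "z"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["participant_id"] = df["participant_id"].astype(str)
        df["centre"] = df["centre"].astype(int)
        df["arm"] = df["arm"].astype(int)
        self.participants = df.reset_index(drop=True)

        if attempts is None:
            attempts = pd.DataFrame(columns=ATTEMPT_COLUMNS)
        att = attempts.copy()
        att["participant_id"] = att["participant_id"].astype(str)
        for col in ("m", "attempt_type", "success"):
            att[col] = att[col].astype(int)
        self.attempts = att.reset_index(drop=True)

        if validate:
            self.validate()

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def y0(self) -> np.ndarray:
        return self.participants["y0"].to_numpy(float)

    @property
    def y1(self) -> np.ndarray:
        return self.participants["y1"].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.participants["z"].to_numpy(float)

    @property
    def centre(self) -> np.ndarray:
        return self.participants["centre"].to_numpy(int)

    @property
    def arm(self) -> np.ndarray:
        return self.participants["arm"].to_numpy(int)

    @property
    def r0(self) -> np.ndarray:
        return (~np.isnan(self.y0)).astype(int)

    @property
    def r1(self) -> np.ndarray:
        return (~np.isnan(self.y1)).astype(int)

    @property
    def rz(self) -> np.ndarray:
        return (~np.isnan(self.z)).astype(int)

    @property
    def has_attempts(self) -> bool:
        return len(self.attempts) > 0

    @property
    def has_proxy(self) -> bool:
        return bool(np.any(self.rz))

    def n_attempts(self) -> pd.Series:
        """Number of recorded attempts per participant (0 if none recorded)."""
        counts = self.attempts.groupby("participant_id").size()
        return (
            self.participants["participant_id"].map(counts).fillna(0).astype(int)
        )

    def records(self) -> Iterable[TrialRecord]:
        att_by_pid: dict[str, list[AttemptRecord]] = {}
        for row in self.attempts.sort_values(["participant_id", "m"]).itertuples():
            att_by_pid.setdefault(row.participant_id, []).append(
                AttemptRecord(int(row.m), int(row.attempt_type), int(row.success))
            )
        for row in self.participants.itertuples():
            yield TrialRecord(
                participant_id=row.participant_id,
                centre=int(row.centre),
                arm=int(row.arm),
                y0=None if np.isnan(row.y0) else float(row.y0),
                y1=None if np.isnan(row.y1) else float(row.y1),
                z=None if np.isnan(row.z) else float(row.z),
                attempts=att_by_pid.get(row.participant_id, []),
            )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.participants
        if df["participant_id"].duplicated().any():
            dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise ValidationError(f"duplicate participant_id {dup!r}")
        if not df["arm"].isin([0, 1]).all():
            raise ValidationError("arm must be 0 (control) or 1 (intervention)")
        if not df["centre"].between(1, N_CENTRES).all():
            raise ValidationError(f"centre must be coded 1..{N_CENTRES}")

        if len(self.attempts):
            known = set(df["participant_id"])
            unknown = set(self.attempts["participant_id"]) - known
            if unknown:
                raise ValidationError(
                    f"attempt rows reference unknown participants: {sorted(unknown)[:5]}"
                )
            if not self.attempts["m"].between(1, MAX_ATTEMPTS).all():
                raise ValidationError(f"attempt index m must lie in 1..{MAX_ATTEMPTS}")
            r1_by_pid = dict(zip(df["participant_id"], self.r1))
            for pid, grp in self.attempts.groupby("participant_id"):
                ms = grp["m"].to_numpy()
                succ = grp["success"].to_numpy()
                _validate_attempt_sequence(ms, succ, pid)
                if int(succ.sum()) != r1_by_pid[pid]:
                    raise ValidationError(
                        f"participant {pid!r}: attempt success pattern inconsistent "
                        f"with final-score presence (r1={r1_by_pid[pid]})"
                    )


# -- standardization -----------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Affine map (y - reference_mean) / pooled_sd frozen from observed scores.

    ``pooled_sd`` is the square root of the within-centre pooled variance of
    the observed scores, matching how the trial's scores were standardized
    before entering the selection regressions.
    """

    reference_mean: float
    pooled_sd: float

    def __post_init__(self):
        if not self.pooled_sd > 0:
            raise ValueError(f"pooled_sd must be > 0, got {self.pooled_sd}")

    @classmethod
    def from_observed(
        cls, scores: Sequence[float] | np.ndarray, centres: Sequence[int] | np.ndarray
    ) -> "Standardizer":
        """Freeze mean and within-centre pooled SD from the observed values."""
        scores = np.asarray(scores, float)
        centres = np.asarray(centres, int)
        obs = ~np.isnan(scores)
        if obs.sum() < 2:
            raise ValueError("need at least two observed scores to standardize")
        mean = float(scores[obs].mean())
        ss, dof = 0.0, 0
        for c in np.unique(centres[obs]):
            vals = scores[obs & (centres == c)]
            if len(vals) > 1:
                ss += float(((vals - vals.mean()) ** 2).sum())
                dof += len(vals) - 1
        if dof == 0:
            raise ValueError("no centre has two observed scores; pooled SD undefined")
        return cls(reference_mean=mean, pooled_sd=float(np.sqrt(ss / dof)))

    def transform(self, scores: np.ndarray | Sequence[float]) -> np.ndarray:
        return (np.asarray(scores, float) - self.reference_mean) / self.pooled_sd

    def inverse_transform(self, std_scores: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.asarray(std_scores, float) * self.pooled_sd + self.reference_mean


def standardize(
    scores: Sequence[float] | np.ndarray, s: Standardizer
) -> np.ndarray:
    """Map observed entries to (y - mean)/sd; NaNs (missing) are preserved."""
    return s.transform(scores)


# -- descriptive tables --------------------------------------------------


class PatternTable:
    """Cross-tabulation of the four missingness patterns by arm, with margins.

    Rows: baseline_only (y0 observed, y1 missing), final_only, neither, both,
    and a total row; columns: intervention, control, total.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def __repr__(self) -> str:
        return repr(self.table)

    @property
    def total(self) -> int:
        return int(self.table.loc["total", "total"])

    def check_margins(self) -> None:
        t = self.table
        body = t.loc[PATTERN_LABELS, ["intervention", "control"]]
        if not (body.sum(axis=0) == t.loc["total", ["intervention", "control"]]).all():
            raise ValidationError("pattern table column margins inconsistent")
        if not (body.sum(axis=1) == t.loc[PATTERN_LABELS, "total"]).all():
            raise ValidationError("pattern table row margins inconsistent")


def missingness_pattern(dataset: TrialDataset) -> PatternTable:
    """Tabulate which of the two outcome scores each participant provided."""
    r0, r1, arm = dataset.r0, dataset.r1, dataset.arm
    pattern = np.select(
        [
            (r0 == 1) & (r1 == 0),
            (r0 == 0) & (r1 == 1),
            (r0 == 0) & (r1 == 0),
            (r0 == 1) & (r1 == 1),
        ],
        PATTERN_LABELS,
        default="",
    )
    rows = {}
    for label in PATTERN_LABELS:
        mask = pattern == label
        rows[label] = [int((mask & (arm == 1)).sum()), int((mask & (arm == 0)).sum())]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["intervention", "control"]
    )
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    out = PatternTable(table)
    out.check_margins()
    return out


def attempts_summary(dataset: TrialDataset) -> pd.DataFrame:
    """Mean observed final score and participant counts by attempt band and arm.

    Bands are 1, 2, 3 and >3 recorded contact attempts. ``n`` counts *all*
    participants in a band (responders and nonresponders); the mean is over
    all observed final scores in the band, and ``proportion`` is the band's
    share of every participant with at least one recorded attempt.
    """
    n_att = dataset.n_attempts().to_numpy()
    has = n_att >= 1
    band = np.select(
        [n_att == 1, n_att == 2, n_att == 3, n_att > 3], ATTEMPT_BANDS, default=""
    )
    y1, arm = dataset.y1, dataset.arm
    n_with_attempts = int(has.sum())
    rows = []
    for b in ATTEMPT_BANDS:
        in_band = band == b
        row: dict[str, float] = {"band": b}
        for arm_val, arm_name in ((1, "intervention"), (0, "control")):
            mask = in_band & (arm == arm_val)
            obs = mask & ~np.isnan(y1)
            row[f"mean_{arm_name}"] = float(y1[obs].mean()) if obs.any() else np.nan
            row[f"n_{arm_name}"] = int(mask.sum())
        row["n"] = int(in_band.sum())
        row["proportion"] = (
            row["n"] / n_with_attempts if n_with_attempts else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("band")


# -- delimited-text IO ---------------------------------------------------


def read_trial_table(
    path,
    attempts_path=None,
    *,
    sep: str = ",",
    na_sentinel: str = "",
) -> TrialDataset:
    """Read a participant CSV (plus optional long-format attempts CSV).

    Missing cells are encoded by ``na_sentinel`` (empty by default). If the
    file carries r-indicator columns they are cross-checked against value
    presence and rejected on disagreement; indicators are always re-derived.
    """
    try:
        df = pd.read_csv(
            path, sep=sep, na_values=[na_sentinel], keep_default_na=False, dtype=str
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in ("participant_id", "centre", "arm") if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    for col in ("centre", "arm", "y0", "y1", "z"):
        if col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise ParseError(
                    f"{path}: line {line}: cannot parse {col}={df[col][bad.idxmax()]!r}"
                )
            df[col] = converted

    for ind, score in (("r0", "y0"), ("r1", "y1"), ("rz", "z")):
        if ind in df.columns and score in df.columns:
            stated = pd.to_numeric(df[ind], errors="coerce")
            derived = (~df[score].isna()).astype(int)
            if not (stated == derived).all():
                line = int((stated != derived).idxmax()) + 2
                raise ValidationError(
                    f"{path}: line {line}: {ind} column inconsistent with {score} presence"
                )
            df = df.drop(columns=[ind])

    attempts = None
    if attempts_path is not None:
        att = pd.read_csv(
            attempts_path, sep=sep, na_values=[na_sentinel], keep_default_na=False
        )
        missing_cols = [c for c in ATTEMPT_COLUMNS if c not in att.columns]
        if missing_cols:
            raise ParseError(f"{attempts_path}: missing required columns {missing_cols}")
        attempts = att
    return TrialDataset(df, attempts)


def write_trial_table(dataset: TrialDataset, path, attempts_path=None, *, sep: str = ",") -> None:
    """Write the participant table (and attempts table) back to CSV."""
    cols = [c for c in PARTICIPANT_COLUMNS if c in dataset.participants.columns]
    dataset.participants[cols].to_csv(path, sep=sep, index=False)
    if attempts_path is not None:
        dataset.attempts[ATTEMPT_COLUMNS].to_csv(attempts_path, sep=sep, index=False)
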