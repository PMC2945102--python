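"""Trial-level data model for the corticosteroid sepsis meta-analysis.

Holds the arm-level 2x2 outcome tables and per-trial covariates for the
14-trial cohort of randomised controlled trials of corticosteroids in severe
sepsis / septic shock (1963-2008), together with CSV I/O in a simple
one-row-per-trial-per-outcome schema, hydrocortisone dose-equivalence
arithmetic, and the descriptive (frequentist) log odds-ratio used by the
funnel-plot diagnostics.

The Bayesian models consume :class:`MetaDataset` objects; build them either
from the built-in cohort (:func:`builtin_cohort` + :func:`dataset_from_trials`)
or from a CSV file (:func:`load_dataset`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "OUTCOMES",
    "ArmCount",
    "Trial",
    "MetaDataset",
    "DataError",
    "CSVParseError",
    "EmptyDatasetError",
    "builtin_cohort",
    "dataset_from_trials",
    "load_dataset",
    "write_cohort_csv",
    "observed_log_or",
    "hydrocortisone_equivalent",
    "classify_dose",
]

#: Recognised outcome names.  The first five are the stratified analyses of
#: the study; the two responder-status shock-reversal outcomes cover the
#: subgroup 2x2 tables reported by three trials.
OUTCOMES = (
    "mortality",
    "shock_reversal",
    "superinfection",
    "gi_bleed",
    "hyperglycemia",
    "shock_reversal_responders",
    "shock_reversal_nonresponders",
)

DOSE_GROUPS = ("high", "low")


class DataError(ValueError):
    """Invalid trial data (count constraints, unknown labels...)."""


class CSVParseError(DataError):
    """Malformed CSV input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class EmptyDatasetError(DataError):
    """A selection (outcome x stratum) matched no trial."""


@dataclass(frozen=True)
class ArmCount:
    """Events / total for one trial arm and one outcome."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise DataError(f"arm total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise DataError(
                f"events must satisfy 0 <= events <= total, got {self.events}/{self.total}"
            )

    @property
    def nonevents(self) -> int:
        return self.total - self.events

    @property
    def rate(self) -> float:
        return self.events / self.total


@dataclass
class Trial:
    """One randomised trial: metadata plus per-outcome 2x2 tables.

    ``outcomes`` maps an outcome name to a ``(steroid, control)`` pair of
    :class:`ArmCount`.  Missing covariates are ``None``.
    """

    trial_id: str
    year: int
    dose_group: str
    steroid_type: str | None = None
    hc_equiv_total_mg: float | None = None
    steroid_days: float | None = None
    taper_days: float | None = None
    age_steroid: float | None = None
    age_placebo: float | None = None
    total_n: int | None = None
    outcomes: dict[str, tuple[ArmCount, ArmCount]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_group not in DOSE_GROUPS:
            raise DataError(f"dose_group must be one of {DOSE_GROUPS}, got {self.dose_group!r}")
        for name in self.outcomes:
            if name not in OUTCOMES:
                raise DataError(f"unknown outcome {name!r}")

    @property
    def age_mean(self) -> float | None:
        """Unweighted mean of the two arm mean ages (``None`` if either missing)."""
        if self.age_steroid is None or self.age_placebo is None:
            return None
        return 0.5 * (self.age_steroid + self.age_placebo)

    def covariates(self) -> dict[str, float | None]:
        return {
            "age_steroid": self.age_steroid,
            "age_placebo": self.age_placebo,
            "age": self.age_mean,
            "hc_equiv_total_mg": self.hc_equiv_total_mg,
            "steroid_days": self.steroid_days,
        }


@dataclass(frozen=True)
class TrialArms:
    """One trial's contribution to a :class:`MetaDataset`."""

    trial_id: str
    steroid: ArmCount
    control: ArmCount
    covariates: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class MetaDataset:
    """An ordered set of trials for a single outcome, ready for pooling."""

    outcome: str
    stratum_label: str
    trials: list[TrialArms]

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise DataError(f"unknown outcome {self.outcome!r}")
        if not self.trials:
            raise EmptyDatasetError(
                f"no trials for outcome={self.outcome!r}, stratum={self.stratum_label!r}"
            )
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate trial ids in dataset: {ids}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    def counts(self) -> tuple[list[int], list[int], list[int], list[int]]:
        """Return (steroid events, steroid totals, control events, control totals)."""
        rt = [t.steroid.events for t in self.trials]
        nt = [t.steroid.total for t in self.trials]
        rc = [t.control.events for t in self.trials]
        nc = [t.control.total for t in self.trials]
        return rt, nt, rc, nc

    def covariate_values(self, name: str) -> list[float | None]:
        return [t.covariates.get(name) for t in self.trials]

    def exclude(self, trial_ids: str | Iterable[str]) -> "MetaDataset":
        if isinstance(trial_ids, str):
            trial_ids = [trial_ids]
        drop = set(trial_ids)
        missing = drop - set(self.trial_ids)
        if missing:
            raise DataError(f"cannot exclude unknown trial(s): {sorted(missing)}")
        kept = [t for t in self.trials if t.trial_id not in drop]
        label = f"{self.stratum_label} - {'-'.join(sorted(drop))}"
        return MetaDataset(self.outcome, label, kept)

    def subset(self, trial_ids: Sequence[str]) -> "MetaDataset":
        by_id = {t.trial_id: t for t in self.trials}
        missing = [tid for tid in trial_ids if tid not in by_id]
        if missing:
            raise DataError(f"unknown trial(s): {missing}")
        return MetaDataset(self.outcome, self.stratum_label, [by_id[t] for t in trial_ids])

    def swap_arms(self) -> "MetaDataset":
        """Exchange steroid and control arms in every trial (for symmetry checks)."""
        swapped = [
            TrialArms(t.trial_id, t.control, t.steroid, dict(t.covariates))
            for t in self.trials
        ]
        return MetaDataset(self.outcome, self.stratum_label + " (arms swapped)", swapped)


# ---------------------------------------------------------------------------
# Built-in cohort
# ---------------------------------------------------------------------------

# Per-trial tuples: (year, dose_group, steroid_type, hc_equiv_total_mg,
# steroid_days, taper_days, age_steroid, age_placebo, total_n).
# Dose-days for bolus/24 h regimens are recorded as 1; ranges as midpoints.
_TRIAL_META: dict[str, tuple] = {
    "CSG 1963": (1963, "low", "hydrocortisone", 1050.0, 1.0, 4.0, None, None, 194),
    "Klastersky 1971": (1971, "high", "betamethasone", 7000.0, 3.0, 0.0, None, None, 85),
    "Schumer 1976": (1976, "high", "methylprednisolone", 8050.0, 1.0, 0.0, 49.0, 51.0, 172),
    "Sprung 1984": (1984, "high", "methylprednisolone", 18884.0, 1.0, 0.0, 56.5, 48.0, 59),
    "Bone 1987": (1987, "high", "methylprednisolone", 42000.0, 1.0, 0.0, 53.0, 53.7, 382),
    "Luce 1988": (1988, "high", "methylprednisolone", 42000.0, 1.0, 0.0, 50.0, 53.0, 75),
    "Bollaert 1998": (1998, "low", "hydrocortisone", 2175.0, 5.0, 6.0, 58.7, 56.8, 41),
    "Briegel 1999": (1999, "low", "hydrocortisone", 2126.0, 3.0, 8.5, 47.0, 51.0, 40),
    "Chawla 1999": (1999, "low", "hydrocortisone", 1350.0, 3.0, 4.0, None, None, 44),
    "Yildiz 2002": (2002, "low", "prednisolone", 300.0, 10.0, 0.0, 57.8, 56.5, 40),
    "Annane 2002": (2002, "low", "hydrocortisone", 1400.0, 7.0, 0.0, 62.0, 60.0, 291),
    "Tandan 2005": (2005, "low", None, None, None, None, None, None, 28),
    "Oppert 2005": (2005, "low", "hydrocortisone", 856.0, 2.5, 3.5, 59.0, 47.0, 41),
    "Sprung 2008": (2008, "low", "hydrocortisone", 1800.0, 5.0, 6.0, 63.0, 63.0, 499),
}

# Outcome counts: trial_id -> outcome -> (steroid events, steroid total,
# control events, control total).
_TRIAL_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "CSG 1963": {
        "mortality": (54, 96, 32, 98),
        "superinfection": (3, 96, 3, 99),
        "gi_bleed": (4, 96, 0, 98),
    },
    "Klastersky 1971": {
        "mortality": (24, 66, 18, 39),
        "superinfection": (11, 46, 6, 39),
    },
    "Schumer 1976": {
        "mortality": (9, 86, 33, 86),
        "gi_bleed": (2, 86, 1, 86),
        "hyperglycemia": (1, 86, 1, 86),
    },
    "Sprung 1984": {
        "mortality": (33, 43, 11, 16),
        "shock_reversal": (25, 43, 6, 16),
        "superinfection": (11, 43, 1, 16),
        "gi_bleed": (1, 43, 2, 32),
        "hyperglycemia": (4, 45, 0, 16),
    },
    "Bone 1987": {
        "mortality": (65, 191, 48, 190),
        "shock_reversal": (85, 130, 83, 114),
        "superinfection": (29, 152, 30, 147),
    },
    "Luce 1988": {
        "mortality": (22, 38, 20, 37),
        "superinfection": (3, 38, 4, 37),
        "gi_bleed": (18, 38, 16, 37),
        "hyperglycemia": (16, 38, 15, 37),
    },
    "Bollaert 1998": {
        "mortality": (7, 22, 12, 19),
        "shock_reversal": (15, 22, 4, 23),
        "shock_reversal_responders": (12, 18, 2, 11),
        "shock_reversal_nonresponders": (3, 4, 2, 8),
        "superinfection": (7, 22, 9, 19),
        "gi_bleed": (1, 22, 3, 19),
        "hyperglycemia": (3, 22, 3, 19),
    },
    "Briegel 1999": {
        "mortality": (5, 20, 6, 20),
        "shock_reversal": (18, 20, 16, 20),
        "superinfection": (10, 20, 7, 20),
        "gi_bleed": (1, 20, 0, 20),
    },
    "Chawla 1999": {
        "mortality": (6, 23, 10, 21),
        "shock_reversal": (16, 23, 7, 21),
    },
    "Yildiz 2002": {
        "mortality": (8, 20, 12, 20),
        "superinfection": (0, 20, 1, 20),
        "hyperglycemia": (0, 20, 0, 20),
    },
    "Annane 2002": {
        "mortality": (95, 160, 103, 150),
        "shock_reversal": (60, 151, 40, 149),
        "shock_reversal_responders": (18, 36, 18, 34),
        "shock_reversal_nonresponders": (65, 114, 46, 115),
        "superinfection": (22, 150, 27, 150),
        "gi_bleed": (11, 150, 8, 149),
    },
    "Tandan 2005": {
        "mortality": (11, 14, 13, 14),
        "shock_reversal": (5, 14, 3, 14),
    },
    "Oppert 2005": {
        "mortality": (7, 18, 11, 23),
        "shock_reversal": (13, 18, 18, 23),
    },
    "Sprung 2008": {
        "mortality": (111, 251, 100, 245),
        "shock_reversal": (200, 251, 184, 248),
        "shock_reversal_responders": (100, 118, 104, 136),
        "shock_reversal_nonresponders": (98, 125, 76, 108),
        "superinfection": (78, 234, 61, 132),
        "gi_bleed": (15, 234, 13, 232),
        "hyperglycemia": (186, 234, 161, 232),
    },
}


def builtin_cohort() -> list[Trial]:
    """The 14-trial study cohort, ordered by publication year.

    Counts and covariates are transcribed from the published trial tables.
    The high-dose stratum (>1,000 mg hydrocortisone-equivalent per day)
    comprises Klastersky 1971, Schumer 1976, Sprung 1984, Bone 1987 and
    Luce 1988; the remaining nine trials are low-dose.
    """
    trials = []
    for tid, meta in _TRIAL_META.items():
        year, group, styp, hc, days, taper, age_s, age_p, total_n = meta
        outcomes = {
            name: (ArmCount(a, n1), ArmCount(b, n0))
            for name, (a, n1, b, n0) in _TRIAL_COUNTS[tid].items()
        }
        trials.append(
            Trial(
                trial_id=tid,
                year=year,
                dose_group=group,
                steroid_type=styp,
                hc_equiv_total_mg=hc,
                steroid_days=days,
                taper_days=taper,
                age_steroid=age_s,
                age_placebo=age_p,
                total_n=total_n,
                outcomes=outcomes,
            )
        )
    trials.sort(key=lambda t: (t.year, t.trial_id))
    return trials


def dataset_from_trials(
    trials: Iterable[Trial],
    outcome: str,
    stratum: str | Sequence[str] = "all",
    exclude: Iterable[str] = (),
) -> MetaDataset:
    """Restrict a trial list to one outcome and stratum.

    ``stratum`` is ``"high"``, ``"low"``, ``"all"`` or an explicit list of
    trial ids; only trials reporting both arms for ``outcome`` are kept.
    """
    trials = list(trials)
    if isinstance(stratum, str):
        if stratum not in ("high", "low", "all"):
            raise DataError(f"stratum must be 'high', 'low', 'all' or a trial-id list, got {stratum!r}")
        keep = [t for t in trials if stratum in ("all", t.dose_group)]
        label = f"{stratum} dose" if stratum != "all" else "all trials"
    else:
        wanted = list(stratum)
        by_id = {t.trial_id: t for t in trials}
        missing = [tid for tid in wanted if tid not in by_id]
        if missing:
            raise DataError(f"unknown trial(s) in stratum list: {missing}")
        keep = [by_id[tid] for tid in wanted]
        label = "selected trials"
    drop = set(exclude)
    keep = [t for t in keep if t.trial_id not in drop]
    rows = [
        TrialArms(t.trial_id, t.outcomes[outcome][0], t.outcomes[outcome][1], t.covariates())
        for t in keep
        if outcome in t.outcomes
    ]
    if not rows:
        raise EmptyDatasetError(f"no trials report outcome {outcome!r} in stratum {label!r}")
    if drop:
        label += f" excl {', '.join(sorted(drop))}"
    return MetaDataset(outcome, label, rows)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "trial_id",
    "year",
    "dose_group",
    "outcome",
    "steroid_events",
    "steroid_total",
    "control_events",
    "control_total",
    "age_steroid",
    "age_placebo",
    "hc_equiv_total_mg",
    "steroid_days",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_cohort_csv(trials: Iterable[Trial], path) -> None:
    """Write trials as CSV, one row per trial per reported outcome."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for t in trials:
            for outcome in OUTCOMES:
                if outcome not in t.outcomes:
                    continue
                s, c = t.outcomes[outcome]
                writer.writerow(
                    [
                        t.trial_id,
                        t.year,
                        t.dose_group,
                        outcome,
                        s.events,
                        s.total,
                        c.events,
                        c.total,
                        _fmt(t.age_steroid),
                        _fmt(t.age_placebo),
                        _fmt(t.hc_equiv_total_mg),
                        _fmt(t.steroid_days),
                    ]
                )


def _parse_float(text: str, name: str, line: int) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise CSVParseError(f"field {name!r} is not numeric: {text!r}", line) from None


def _parse_int(text: str, name: str, line: int) -> int:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        raise CSVParseError(f"field {name!r} is not an integer: {text!r}", line) from None


def load_trials_csv(path) -> list[Trial]:
    """Parse the CSV schema back into :class:`Trial` objects (file order)."""
    trials: dict[str, Trial] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(CSV_COLUMNS):
            raise CSVParseError(f"expected header {','.join(CSV_COLUMNS)}", 1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                raise CSVParseError(f"expected {len(CSV_COLUMNS)} fields, got {len(row)}", lineno)
            rec = dict(zip(CSV_COLUMNS, row))
            tid = rec["trial_id"].strip()
            if not tid:
                raise CSVParseError("empty trial_id", lineno)
            outcome = rec["outcome"].strip()
            if outcome not in OUTCOMES:
                raise CSVParseError(f"unknown outcome {outcome!r}", lineno)
            try:
                steroid = ArmCount(
                    _parse_int(rec["steroid_events"], "steroid_events", lineno),
                    _parse_int(rec["steroid_total"], "steroid_total", lineno),
                )
                control = ArmCount(
                    _parse_int(rec["control_events"], "control_events", lineno),
                    _parse_int(rec["control_total"], "control_total", lineno),
                )
            except DataError as exc:
                raise CSVParseError(str(exc), lineno) from None
            if tid not in trials:
                try:
                    trials[tid] = Trial(
                        trial_id=tid,
                        year=_parse_int(rec["year"], "year", lineno),
                        dose_group=rec["dose_group"].strip(),
                        age_steroid=_parse_float(rec["age_steroid"], "age_steroid", lineno),
                        age_placebo=_parse_float(rec["age_placebo"], "age_placebo", lineno),
                        hc_equiv_total_mg=_parse_float(
                            rec["hc_equiv_total_mg"], "hc_equiv_total_mg", lineno
                        ),
                        steroid_days=_parse_float(rec["steroid_days"], "steroid_days", lineno),
                    )
                except DataError as exc:
                    raise CSVParseError(str(exc), lineno) from None
            if outcome in trials[tid].outcomes:
                raise CSVParseError(f"duplicate outcome {outcome!r} for trial {tid!r}", lineno)
            trials[tid].outcomes[outcome] = (steroid, control)
    return list(trials.values())


def load_dataset(path, outcome: str, stratum: str | Sequence[str] = "all") -> MetaDataset:
    """Load a CSV file and restrict it to one outcome and dose stratum."""
    return dataset_from_trials(load_trials_csv(path), outcome, stratum)


# ---------------------------------------------------------------------------
# Descriptive statistics and dose arithmetic
# ---------------------------------------------------------------------------


def observed_log_or(
    steroid: ArmCount, control: ArmCount, correction: float = 0.5
) -> tuple[float, float]:
    """Observed log odds-ratio (steroid vs control) and its standard error.

    A continuity ``correction`` is added to all four cells of the 2x2 table
    only when some cell is zero; with ``correction=0`` a zero cell raises.
    The Bayesian binomial models use the raw counts and never need this.
    """
    if correction < 0:
        raise DataError("correction must be >= 0")
    cells = [
        float(steroid.events),
        float(steroid.nonevents),
        float(control.events),
        float(control.nonevents),
    ]
    if any(c == 0 for c in cells):
        if correction == 0:
            raise DataError(
                "2x2 table has a zero cell; the odds ratio is infinite without a correction"
            )
        cells = [c + correction for c in cells]
    a, b, c, d = cells
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


#: Glucocorticoid potency relative to hydrocortisone (standard equivalence table).
HC_EQUIVALENCE = {
    "hydrocortisone": 1.0,
    "prednisolone": 4.0,
    "methylprednisolone": 5.0,
    "dexamethasone": 26.7,
    "betamethasone": 26.7,
}


def hydrocortisone_equivalent(drug: str, dose_mg: float) -> float:
    """Convert a glucocorticoid dose (mg) into hydrocortisone-equivalent mg."""
    if dose_mg < 0:
        raise DataError("dose must be >= 0")
    try:
        return dose_mg * HC_EQUIVALENCE[drug]
    except KeyError:
        raise DataError(
            f"unknown glucocorticoid {drug!r}; known: {sorted(HC_EQUIVALENCE)}"
        ) from None


def classify_dose(trial: Trial) -> str:
    """High- vs low-dose classification: >1,000 hydrocortisone-equivalent mg/day.

    The daily dose divides the total realizable hydrocortisone-equivalent dose
    by the total days of exposure (treatment plus tapering).  When the dose
    metadata are missing the stored ``dose_group`` label is authoritative.
    """
    if trial.hc_equiv_total_mg is not None and trial.steroid_days is not None:
        days = trial.steroid_days + (trial.taper_days or 0.0)
        if days > 0:
            return "high" if trial.hc_equiv_total_mg / days > 1000.0 else "low"
    if trial.dose_group in DOSE_GROUPS:
        return trial.dose_group
    raise DataError(f"trial {trial.trial_id!r} has neither dose metadata nor a dose_group label")
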