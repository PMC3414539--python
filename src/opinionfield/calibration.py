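"""Survey ingestion and field-strength calibration.

The package ships a two-survey table (a European and a Mexican science
perception questionnaire) of 15 paired statements with agreement and
disagreement percentages.  Residual answers ("do not know" / "neither")
carry protocol dependence and are excluded: a statement's agreement
fraction is ``yes / (yes + no)``.

Calibration matches those fractions against the model: a Monte-Carlo
response curve ``<n+>(h)`` is built by running the simulator over a field
grid, isotonic smoothing enforces the monotonicity the inversion needs, and
each statement is assigned the field strength whose simulated agreement
fraction coincides with the survey's.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import ValidationError
from .model_core import ModelParams, run_simulation
from .observables import agreement_count_fraction

__all__ = [
    "SurveyRecord",
    "SurveyTable",
    "ResponseCurve",
    "FieldAssignment",
    "PACKAGED_SURVEYS",
    "load_survey",
    "agreement_fraction",
    "build_response_curve",
    "assign_fields",
]

PACKAGED_SURVEYS = ("EU", "Mx")


@dataclass(frozen=True)
class SurveyRecord:
    label: str
    text: str
    yes_pct: float
    no_pct: float

    @property
    def other_pct(self) -> float:
        """Residual do-not-know / neither mass."""
        return 100.0 - self.yes_pct - self.no_pct


@dataclass
class SurveyTable:
    survey_id: str
    records: list[SurveyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def agreement_fractions(self) -> list[float]:
        return [agreement_fraction(r.yes_pct, r.no_pct) for r in self.records]


def agreement_fraction(yes_pct: float, no_pct: float) -> float:
    """``yes / (yes + no)``, excluding residual answers."""
    total = yes_pct + no_pct
    if total <= 0:
        raise ValidationError(
            f"agreement fraction undefined for yes={yes_pct}, no={no_pct}"
        )
    return yes_pct / total


def _validate_rows(survey_id: str, rows: list[dict]) -> SurveyTable:
    table = SurveyTable(survey_id=survey_id)
    seen: set[str] = set()
    for row in rows:
        label = row["label"]
        try:
            yes = float(row["yes_pct"])
            no = float(row["no_pct"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"survey {survey_id} row {label!r}: non-numeric percentage"
            ) from exc
        if label in seen:
            raise ValidationError(f"survey {survey_id}: duplicate label {label!r}")
        if yes < 0 or no < 0:
            raise ValidationError(
                f"survey {survey_id} row {label!r}: negative percentage"
            )
        if yes + no > 100.0 + 1e-9:
            raise ValidationError(
                f"survey {survey_id} row {label!r}: yes + no = {yes + no} > 100"
            )
        seen.add(label)
        table.records.append(
            SurveyRecord(label=label, text=row.get("text", ""), yes_pct=yes, no_pct=no)
        )
    if not table.records:
        raise ValidationError(f"survey {survey_id} has no records")
    return table


def _read_survey_csv(fh) -> dict[str, list[dict]]:
    by_survey: dict[str, list[dict]] = {}
    for row in csv.DictReader(fh):
        missing = {"survey_id", "label", "yes_pct", "no_pct"} - set(row)
        if missing:
            raise ValidationError(f"survey CSV missing columns: {sorted(missing)}")
        by_survey.setdefault(row["survey_id"], []).append(row)
    return by_survey


def load_survey(source: str | Path) -> SurveyTable:
    """Load and validate one survey table.

    ``source`` is either a packaged survey id (``"EU"`` or ``"Mx"``) or a
    path to a CSV with columns ``survey_id,label,text,yes_pct,no_pct``.
    A file holding several surveys must be disambiguated by the packaged-id
    form ``path::survey_id``.
    """
    wanted = None
    if isinstance(source, str) and source in PACKAGED_SURVEYS:
        ref = resources.files("opinionfield.data") / "surveys.csv"
        with ref.open() as fh:
            by_survey = _read_survey_csv(fh)
        wanted = source
    else:
        path = str(source)
        if "::" in path:
            path, wanted = path.rsplit("::", 1)
        with open(path) as fh:
            by_survey = _read_survey_csv(fh)
    if wanted is None:
        if len(by_survey) != 1:
            raise ValidationError(
                f"file holds surveys {sorted(by_survey)}; append '::<id>' to pick one"
            )
        wanted = next(iter(by_survey))
    if wanted not in by_survey:
        raise ValidationError(f"survey {wanted!r} not found in {sorted(by_survey)}")
    return _validate_rows(wanted, by_survey[wanted])


# ---------------------------------------------------------------------------
# response curve
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurve:
    """Monotone map between field strength and mean model agreement."""

    h_grid: np.ndarray
    mean_agreement: np.ndarray
    sd_agreement: np.ndarray
    fitted: np.ndarray  # isotonic (non-decreasing) values on h_grid
    replicates: int
    seeds: list[list[int]]

    def predict(self, h: float) -> float:
        return float(np.interp(h, self.h_grid, self.fitted))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.fitted.min()), float(self.fitted.max())

    def invert(self, n_agree: float) -> tuple[float, bool]:
        """Field strength whose fitted agreement equals ``n_agree``.

        Values outside the fitted range clamp to the nearest grid endpoint
        and are flagged.  Inside flat segments the leftmost matching grid
        position is returned (deterministic).
        """
        lo, hi = self.span
        if hi - lo < 1e-9:
            raise ValidationError("response curve is degenerate (constant)")
        if n_agree <= lo:
            return float(self.h_grid[int(np.argmax(self.fitted == lo))]), n_agree < lo
        if n_agree >= hi:
            return float(self.h_grid[int(np.argmax(self.fitted == hi))]), n_agree > hi
        # strictly-increasing envelope for interpolation
        keep = np.concatenate(([True], np.diff(self.fitted) > 0))
        return float(np.interp(n_agree, self.fitted[keep], self.h_grid[keep])), False


def build_response_curve(
    params: ModelParams,
    h_grid,
    replicates: int,
    seed: int | None = None,
) -> ResponseCurve:
    """Monte-Carlo mean agreement fraction over a field grid.

    For every grid value the simulator runs ``replicates`` times to its
    horizon and the final agreement fractions are averaged; an isotonic
    regression then smooths the means into the non-decreasing curve the
    survey inversion requires.  Run seeds are derived deterministically from
    ``seed`` (defaulting to ``params.seed``) and stored on the curve.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    h_grid = np.asarray(sorted(h_grid), dtype=float)
    if h_grid.size < 2:
        raise ValidationError("h_grid needs at least two values")
    base = params.seed if seed is None else seed
    means, sds, all_seeds = [], [], []
    for i, h in enumerate(h_grid):
        ss = np.random.SeedSequence(entropy=base, spawn_key=(i,))
        run_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(replicates)]
        vals = []
        for s in run_seeds:
            r = run_simulation(params.with_(field=float(h), seed=s))
            frac = agreement_count_fraction(r.states, params.agreement_frozen_only)
            if frac is not None:
                vals.append(frac)
        means.append(float(np.mean(vals)) if vals else np.nan)
        sds.append(float(np.std(vals)) if vals else np.nan)
        all_seeds.append(run_seeds)
    means_arr = np.asarray(means)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(h_grid, means_arr)
    return ResponseCurve(
        h_grid=h_grid,
        mean_agreement=means_arr,
        sd_agreement=np.asarray(sds),
        fitted=np.asarray(fitted, dtype=float),
        replicates=replicates,
        seeds=all_seeds,
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatementField:
    label: str
    agreement: float  # n_A
    field: float  # assigned h
    clamped: bool


@dataclass
class FieldAssignment:
    survey_id: str
    entries: list[StatementField]

    def to_rows(self) -> list[dict]:
        return [
            {
                "survey_id": self.survey_id,
                "label": e.label,
                "n_A": e.agreement,
                "h": e.field,
                "clamped": e.clamped,
            }
            for e in self.entries
        ]


def assign_fields(table: SurveyTable, curve: ResponseCurve) -> FieldAssignment:
    """Invert every statement's agreement fraction through the curve."""
    entries = []
    for rec in table.records:
        n_a = agreement_fraction(rec.yes_pct, rec.no_pct)
        h, clamped = curve.invert(n_a)
        entries.append(
            StatementField(label=rec.label, agreement=n_a, field=h, clamped=clamped)
        )
    return FieldAssignment(survey_id=table.survey_id, entries=entries)
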