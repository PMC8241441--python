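"""Plain-text session and result I/O.

Sessions are stored as comma-separated event tables (UTF-8, "." decimal,
header row, ``#``-prefixed metadata lines) with one row per event: trial
rows carry the gamble economics and rating rows carry the mood value; the
unused columns of each row type are left empty.  Floats are written with
Python's shortest round-tripping representation, so
``read_sessions(write_sessions(x)) == x`` exactly.  Mood is stored on the
normalized [0, 1] scale; the original scale range, seed, and config digest
travel in the metadata header.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .agents import ChoicePolicy, PopulationSpec
from .fitting import FitConfig, FitResult
from .tasks import TaskConfig
from .types import (
    CANONICAL_SPECS,
    ModelSpec,
    MoodObservation,
    Session,
    TrialRecord,
)

__all__ = [
    "ParseError",
    "DataIntegrityError",
    "MappingNeededError",
    "write_sessions",
    "read_sessions",
    "write_fit_result",
    "RunConfig",
    "osf_adapter",
    "write_mapping_template",
    "resolve_model_spec",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_COLUMNS = [
    "subject_id",
    "task_kind",
    "event_type",
    "trial_index",
    "block_id",
    "high",
    "low",
    "certain",
    "chose_gamble",
    "outcome",
    "rpe",
    "congruent",
    "rating_index",
    "after_trial",
    "mood_value",
]


class ParseError(ValueError):
    """Malformed file content; the message names the offending line."""


class DataIntegrityError(ValueError):
    """Well-formed file whose content violates a session invariant."""


class MappingNeededError(ValueError):
    """External data layout not covered by the provided column mapping."""


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    return repr(float(value)) if isinstance(value, float) else str(value)


def write_sessions(
    sessions: Sequence[Session],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Serialize sessions to one event table; lossless round trip."""
    path = Path(path)
    meta = {"schema_version": SCHEMA_VERSION, "mood_scale": "0..1 (normalized)"}
    meta.update(metadata or {})
    with path.open("w", newline="", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for session in sessions:
            for tr in session.trials:
                writer.writerow(
                    [
                        session.subject_id,
                        session.task_kind,
                        "trial",
                        tr.index,
                        tr.block_id,
                        _fmt(float(tr.high)),
                        _fmt(float(tr.low)),
                        _fmt(float(tr.certain)),
                        _fmt(tr.chose_gamble),
                        _fmt(float(tr.outcome)),
                        _fmt(float(tr.outcome - tr.gamble_mean)),
                        _fmt(tr.congruent),
                        "",
                        "",
                        "",
                    ]
                )
            for obs in session.ratings:
                writer.writerow(
                    [
                        session.subject_id,
                        session.task_kind,
                        "rating",
                        "",
                        "",
                        "",
                        "",
                        "",
                        "",
                        "",
                        "",
                        "",
                        obs.rating_index,
                        obs.after_trial,
                        _fmt(float(obs.value)),
                    ]
                )


def _parse_row(row: dict, line: int):
    try:
        kind = row["event_type"]
        if kind == "trial":
            return row["subject_id"], row["task_kind"], TrialRecord(
                index=int(row["trial_index"]),
                high=float(row["high"]),
                low=float(row["low"]),
                certain=float(row["certain"]),
                chose_gamble=row["chose_gamble"] == "1",
                outcome=float(row["outcome"]),
                block_id=int(row["block_id"]),
                congruent=row["congruent"] == "1",
            )
        if kind == "rating":
            return row["subject_id"], row["task_kind"], MoodObservation(
                rating_index=int(row["rating_index"]),
                after_trial=int(row["after_trial"]),
                value=float(row["mood_value"]),
            )
        raise ValueError(f"unknown event_type {kind!r}")
    except (KeyError, TypeError, ValueError) as err:
        raise ParseError(f"line {line}: {err}") from err


def read_sessions(path: str | Path, validate: bool = True) -> list[Session]:
    """Read an event table back into sessions, checking the invariants.

    Raises :class:`ParseError` naming the offending line for malformed rows
    and :class:`DataIntegrityError` naming the offending record for
    invariant violations (e.g. a rating gap outside 2-3 trials).  An empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    by_subject: dict[str, Session] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        header_lines = 0
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header_lines += 1
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty session file", stacklevel=2)
            return []
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(
                f"line {header_lines + 1}: missing columns {sorted(missing)}"
            )
        n_rows = 0
        for i, row in enumerate(reader):
            n_rows += 1
            line_no = header_lines + 2 + i
            sid, task_kind, record = _parse_row(row, line_no)
            session = by_subject.setdefault(sid, Session(sid, task_kind))
            if isinstance(record, TrialRecord):
                session.trials.append(record)
            else:
                session.ratings.append(record)
    if n_rows == 0:
        warnings.warn(f"{path}: session file has no event rows", stacklevel=2)
    sessions = list(by_subject.values())
    if validate:
        for session in sessions:
            try:
                session.validate()
            except ValueError as err:
                raise DataIntegrityError(str(err)) from err
    return sessions


def write_fit_result(fit: FitResult, path: str | Path, metadata: dict | None = None) -> None:
    """Tidy per-subject parameter table for a fitted cohort."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        meta = {
            "model": fit.spec.name,
            "objective": fit.objective,
            "converged": fit.converged,
        }
        meta.update(metadata or {})
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["subject", "m0", "beta_c", "beta_e", "beta_r", "xi", "gamma", "training_mse"]
        )
        for s, (p, mse) in enumerate(zip(fit.params, fit.training_mse)):
            writer.writerow(
                [s, _fmt(p.m0), _fmt(p.beta_c), _fmt(p.beta_e), _fmt(p.beta_r),
                 _fmt(p.xi), _fmt(p.gamma), _fmt(float(mse))]
            )


def resolve_model_spec(name: str) -> ModelSpec:
    """Look up a canonical model by name, or parse a decayed-window label of
    the form ``decayed_window_w<decay>_t<t_max>``."""
    if name in CANONICAL_SPECS:
        return CANONICAL_SPECS[name]
    if name.startswith("decayed_window_w"):
        from .types import decayed_window_spec

        body = name.removeprefix("decayed_window_w")
        try:
            w_str, t_str = body.split("_t")
            return decayed_window_spec(float(w_str), int(t_str))
        except ValueError as err:
            raise ValueError(f"cannot parse decayed-window label {name!r}") from err
    raise ValueError(
        f"unknown model {name!r}; available: {sorted(CANONICAL_SPECS)}"
    )


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    task_kind: str = "structured"
    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    model_names: tuple[str, ...] = ("primacy", "recency")
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["population"]["generating_model"] = self.population.generating_model.name
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        pop = dict(d.get("population", {}))
        if "generating_model" in pop:
            pop["generating_model"] = resolve_model_spec(pop["generating_model"])
        if "choice_policy" in pop:
            pop["choice_policy"] = ChoicePolicy(**pop["choice_policy"])
        if "beta_scales" in pop:
            pop["beta_scales"] = tuple(
                (str(k), float(v)) for k, v in pop["beta_scales"]
            )
        if "m0_range" in pop:
            pop["m0_range"] = tuple(pop["m0_range"])
        task = dict(d.get("task", {}))
        for key in ("rating_gap_choices", "block_rpes", "mood_targets",
                    "random_mean_grid", "high_grid"):
            if key in task:
                task[key] = tuple(task[key])
        return cls(
            task_kind=d.get("task_kind", "structured"),
            task=TaskConfig(**task),
            population=PopulationSpec(**pop),
            model_names=tuple(d.get("model_names", ("primacy", "recency"))),
            fit=FitConfig(**d.get("fit", {})),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "."),
        )

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# external (deposited) data adapter

_MAPPING_KEYS = (
    "subject", "trial", "high", "low", "certain", "chose_gamble", "outcome",
    "mood",
)


def write_mapping_template(path: str | Path) -> None:
    """Template column mapping for externally deposited trial-wise tables.

    Edit the right-hand side to the column names of the downloaded file;
    ``mood_scale`` gives the raw rating range, normalized to [0, 1] on load.
    """
    template = {
        "delimiter": ",",
        "task_kind": "structured_adaptive",
        "mood_scale": [0.0, 1.0],
        "columns": {key: key for key in _MAPPING_KEYS},
    }
    Path(path).write_text(yaml.safe_dump(template, sort_keys=False))


def osf_adapter(path: str | Path, mapping_path: str | Path) -> list[Session]:
    """Load externally deposited trial-wise tables into sessions.

    ``path`` is a locally downloaded delimited file with one row per trial
    and the mood rating (if any) on the row of the trial it followed;
    ``mapping_path`` is the edited output of
    :func:`write_mapping_template`.  Never downloads anything: an absent
    file is reported cleanly, and an unrecognized layout raises
    :class:`MappingNeededError` naming the missing columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: deposited data not present; download it manually and "
            "point the adapter at the local copy"
        )
    mapping = yaml.safe_load(Path(mapping_path).read_text())
    columns = mapping.get("columns", {})
    missing = [k for k in _MAPPING_KEYS if k not in columns]
    if missing:
        raise MappingNeededError(
            f"mapping file lacks entries for {missing}; edit the mapping "
            "template to name the deposited columns"
        )
    lo, hi = (float(v) for v in mapping.get("mood_scale", [0.0, 1.0]))
    if hi <= lo:
        raise MappingNeededError("mood_scale must be an increasing pair")
    task_kind = mapping.get("task_kind", "structured_adaptive")
    delimiter = mapping.get("delimiter", ",")

    by_subject: dict[str, Session] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = set(reader.fieldnames or [])
        absent = [v for v in columns.values() if v not in header]
        if absent:
            raise MappingNeededError(
                f"{path}: columns {absent} not found in file header "
                f"{sorted(header)}"
            )
        for i, row in enumerate(reader):
            line_no = i + 2
            try:
                sid = str(row[columns["subject"]])
                session = by_subject.setdefault(sid, Session(sid, task_kind))
                trial = TrialRecord(
                    index=int(float(row[columns["trial"]])),
                    high=float(row[columns["high"]]),
                    low=float(row[columns["low"]]),
                    certain=float(row[columns["certain"]]),
                    chose_gamble=bool(int(float(row[columns["chose_gamble"]]))),
                    outcome=float(row[columns["outcome"]]),
                )
                session.trials.append(trial)
                raw_mood = row.get(columns["mood"], "")
                if raw_mood not in ("", None):
                    session.ratings.append(
                        MoodObservation(
                            rating_index=len(session.ratings) + 1,
                            after_trial=trial.index,
                            value=(float(raw_mood) - lo) / (hi - lo),
                        )
                    )
            except (KeyError, TypeError, ValueError) as err:
                raise ParseError(f"{path} line {line_no}: {err}") from err
    return list(by_subject.values())
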