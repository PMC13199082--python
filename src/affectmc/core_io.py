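"""Domain types and I/O for turn-level human-AI interaction logs.

The analysis operates on long-format dialogue logs: one row per turn,
carrying the participant id, a turn index, the user's emotional-valence
state (negative / neutral / positive) and the quality label assigned to
the AI response that followed that turn (low / medium / high).  The
quality label on a row is attached to the transition it precedes, i.e.
the AI response emitted between the state on that row and the state on
the next row; the final row of each participant therefore has no quality.

This module owns the enumerations, the ``InteractionSequence`` and
``TransitionData`` containers, CSV ingestion/serialisation, transition
extraction at Markov order 1 or 2, and the JSON model-artifact format.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import IO, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("affectmc")

MODEL_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Raised when an interaction log or scale file cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a model artifact has an unexpected schema."""


class EmotionState(IntEnum):
    """Discretised emotional valence of a dialogue turn.

    The integer values fix an indexing order (negative < neutral <
    positive) used for array layout only; they carry no metric meaning.
    """

    NEGATIVE = 0
    NEUTRAL = 1
    POSITIVE = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, token: str) -> "EmotionState":
        try:
            return _STATE_ALIASES[str(token).strip().lower()]
        except KeyError:
            raise ParseError(f"unknown emotional state token: {token!r}") from None


class QualityLevel(IntEnum):
    """Expert-assigned quality of one AI response (ordinal low < medium < high)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, token: str) -> "QualityLevel":
        try:
            return _QUALITY_ALIASES[str(token).strip().lower()]
        except KeyError:
            raise ParseError(f"unknown quality token: {token!r}") from None


class StabilityGroup(IntEnum):
    """Trait emotional-stability group from the pre-test clustering."""

    LOW = 0
    HIGH = 1

    @property
    def label(self) -> str:
        return "low" if self is StabilityGroup.LOW else "high"

    @classmethod
    def parse(cls, token: str) -> "StabilityGroup":
        try:
            return _GROUP_ALIASES[str(token).strip().lower()]
        except KeyError:
            raise ParseError(f"unknown stability-group token: {token!r}") from None


_STATE_ALIASES = {
    "n": EmotionState.NEGATIVE,
    "negative": EmotionState.NEGATIVE,
    "u": EmotionState.NEUTRAL,
    "neutral": EmotionState.NEUTRAL,
    "p": EmotionState.POSITIVE,
    "positive": EmotionState.POSITIVE,
}

_QUALITY_ALIASES = {
    "l": QualityLevel.LOW,
    "low": QualityLevel.LOW,
    "m": QualityLevel.MEDIUM,
    "medium": QualityLevel.MEDIUM,
    "h": QualityLevel.HIGH,
    "high": QualityLevel.HIGH,
}

_GROUP_ALIASES = {
    "l": StabilityGroup.LOW,
    "low": StabilityGroup.LOW,
    "lowstability": StabilityGroup.LOW,
    "low_stability": StabilityGroup.LOW,
    "h": StabilityGroup.HIGH,
    "high": StabilityGroup.HIGH,
    "highstability": StabilityGroup.HIGH,
    "high_stability": StabilityGroup.HIGH,
}

N_STATES = len(EmotionState)
N_QUALITY = len(QualityLevel)


@dataclass
class InteractionSequence:
    """One participant's ordered valence states and per-turn quality labels.

    ``qualities[t]`` is the quality of the AI response emitted between
    ``states[t]`` and ``states[t + 1]``, so ``len(qualities)`` is always
    ``len(states) - 1``.
    """

    participant_id: str
    states: list[EmotionState]
    qualities: list[QualityLevel]
    group: StabilityGroup | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a sequence needs at least one state")
        if len(self.qualities) != len(self.states) - 1:
            raise ValueError(
                f"participant {self.participant_id!r}: expected "
                f"{len(self.states) - 1} quality labels, got {len(self.qualities)}"
            )

    @property
    def n_transitions(self) -> int:
        return len(self.states) - 1


class TransitionRecord(NamedTuple):
    """One extracted transition: (state context, quality covariate, next state)."""

    context: tuple[EmotionState, ...]
    quality: QualityLevel
    next: EmotionState
    group: StabilityGroup | None


@dataclass
class TransitionData:
    """Transitions extracted at a fixed Markov order; the unit the model fits."""

    order: int
    records: list[TransitionRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.context) != self.order:
                raise ValueError(
                    f"record context length {len(rec.context)} != order {self.order}"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def groups(self) -> set[StabilityGroup | None]:
        return {rec.group for rec in self.records}

    def subset_group(self, group: StabilityGroup) -> "TransitionData":
        return TransitionData(
            self.order, [r for r in self.records if r.group is group]
        )


DEFAULT_DIALECT = {
    "participant_id": "participant_id",
    "turn_index": "turn_index",
    "state": "state",
    "quality": "quality",
    "group": "group",
}


def _as_text_handle(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_interaction_log(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> list[InteractionSequence]:
    """Parse a long-format interaction log into per-participant sequences.

    Parameters
    ----------
    source
        Path or open text stream of a UTF-8 CSV with header.
    dialect
        Optional map from the canonical column names
        (``participant_id``, ``turn_index``, ``state``, ``quality`` and
        optionally ``group``) to the names used in the file.

    Rows are sorted by ``turn_index`` within participant; the quality on
    a participant's final row may be empty (there is no following state)
    and is dropped with a logged note.  Missing quality anywhere else,
    duplicate turn indices, or unknown state/quality tokens raise
    :class:`ParseError`.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    handle, should_close = _as_text_handle(source)
    try:
        try:
            frame = pd.read_csv(handle, dtype=str, skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            raise ParseError("empty interaction log") from None
    finally:
        if should_close:
            handle.close()
    if frame.empty:
        raise ParseError("interaction log has a header but no rows")

    required = ["participant_id", "turn_index", "state", "quality"]
    missing = [cols[c] for c in required if cols[c] not in frame.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    has_group = cols["group"] in frame.columns

    frame = frame.rename(columns={v: k for k, v in cols.items()})
    frame["turn_index"] = pd.to_numeric(frame["turn_index"], errors="raise")

    sequences: list[InteractionSequence] = []
    # groupby(sort=False) keeps first-appearance participant order, which
    # makes read -> write -> read a fixed point.
    for pid, rows in frame.groupby("participant_id", sort=False):
        if rows["turn_index"].duplicated().any():
            dup = rows.loc[rows["turn_index"].duplicated(), "turn_index"].iloc[0]
            raise ParseError(
                f"duplicate turn_index {dup} for participant {pid!r}"
            )
        rows = rows.sort_values("turn_index")
        states = [EmotionState.parse(tok) for tok in rows["state"]]
        qual_tokens = list(rows["quality"])
        last = qual_tokens[-1]
        if last is None or (isinstance(last, float) and np.isnan(last)) or str(last).strip() == "":
            logger.debug(
                "participant %s: dropping empty quality on final turn", pid
            )
            qual_tokens = qual_tokens[:-1]
        else:
            qual_tokens = qual_tokens[:-1] + [last]
        qualities = []
        for i, tok in enumerate(qual_tokens):
            if tok is None or (isinstance(tok, float) and np.isnan(tok)) or str(tok).strip() == "":
                raise ParseError(
                    f"participant {pid!r}: missing quality on non-final row {i}"
                )
            qualities.append(QualityLevel.parse(tok))
        if len(qualities) == len(states):
            # final row carried a quality label with no following state
            logger.debug(
                "participant %s: dropping quality on final turn (no next state)",
                pid,
            )
            qualities = qualities[:-1]
        group = None
        if has_group:
            tok = rows["group"].iloc[0]
            if not (tok is None or (isinstance(tok, float) and np.isnan(tok)) or str(tok).strip() == ""):
                group = StabilityGroup.parse(tok)
        sequences.append(
            InteractionSequence(str(pid), states, qualities, group=group)
        )
    return sequences


def write_interaction_log(
    sequences: Iterable[InteractionSequence], sink: str | Path | IO[str]
) -> None:
    """Serialise sequences to canonical CSV (full-word labels, 0-based turns)."""
    seqs = list(sequences)
    any_group = any(s.group is not None for s in seqs)
    rows = []
    for seq in seqs:
        for t, state in enumerate(seq.states):
            row = {
                "participant_id": seq.participant_id,
                "turn_index": t,
                "state": state.label,
                "quality": seq.qualities[t].label if t < len(seq.qualities) else "",
            }
            if any_group:
                row["group"] = seq.group.label if seq.group is not None else ""
            rows.append(row)
    frame = pd.DataFrame(rows)
    if isinstance(sink, (str, Path)):
        frame.to_csv(sink, index=False)
    else:
        frame.to_csv(sink, index=False)


def extract_transitions(
    sequences: Sequence[InteractionSequence], order: int
) -> TransitionData:
    """Extract (context, quality, next-state) records at the given Markov order.

    Order 1 emits one record per consecutive state pair; order 2 emits one
    per consecutive triple (the leading turns of each sequence, which lack
    a full context, are dropped — the study's handling of the missing
    previous time point).  Records never cross participants, and sequences
    shorter than ``order + 1`` states contribute nothing.
    """
    if order not in (1, 2):
        raise ValueError(
            f"unsupported Markov order {order}; orders 1 and 2 are implemented "
            "(higher orders would need a context-index extension)"
        )
    if not sequences:
        raise ValueError("no sequences provided")
    records: list[TransitionRecord] = []
    for seq in sequences:
        for t in range(order - 1, seq.n_transitions):
            context = tuple(seq.states[t - order + 1 : t + 1])
            records.append(
                TransitionRecord(
                    context=context,
                    quality=seq.qualities[t],
                    next=seq.states[t + 1],
                    group=seq.group,
                )
            )
    return TransitionData(order=order, records=records)


# ---------------------------------------------------------------------------
# model artifact (JSON)
# ---------------------------------------------------------------------------

def write_model(fit, sink: str | Path | IO[str]) -> None:
    """Serialise a :class:`~affectmc.cdmc.FitResult` to a JSON document.

    The document stores coefficients at full precision along with the
    metadata needed to reconstruct the fit: order, parameterization,
    reference categories, label order, log-likelihood, parameter count,
    sample size, information criteria, covariance and convergence state.
    """
    params = fit.params
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model": "cdmc",
        "order": params.order,
        "parameterization": params.parameterization,
        "ref_next_state": EmotionState(params.ref_next).label,
        "ref_quality": QualityLevel(params.ref_quality).label,
        "state_labels": [s.label for s in EmotionState],
        "quality_labels": [q.label for q in QualityLevel],
        "coefficients": np.asarray(params.coef).tolist(),
        "coefficient_names": fit.coef_names(),
        "vcov": None if fit.vcov is None else np.asarray(fit.vcov).tolist(),
        "logL": fit.logL,
        "k": fit.k,
        "n": fit.n,
        "aic": fit.aic,
        "bic": fit.bic,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "separation": list(fit.separation),
        "seed": fit.seed,
    }
    text = json.dumps(doc, indent=2)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def read_model(source: str | Path | IO[str]):
    """Load a model artifact written by :func:`write_model`."""
    from . import cdmc  # local import to avoid a module cycle

    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    doc = json.loads(text)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported model schema_version {doc.get('schema_version')!r}; "
            f"expected {MODEL_SCHEMA_VERSION}"
        )
    for key in ("order", "parameterization", "coefficients", "logL", "k", "n"):
        if key not in doc:
            raise SchemaError(f"model document missing field {key!r}")
    params = cdmc.CDMCParameters(
        order=int(doc["order"]),
        parameterization=doc["parameterization"],
        coef=np.asarray(doc["coefficients"], dtype=float),
        ref_next=EmotionState.parse(doc["ref_next_state"]),
        ref_quality=QualityLevel.parse(doc["ref_quality"]),
    )
    vcov = doc.get("vcov")
    return cdmc.FitResult(
        params=params,
        logL=float(doc["logL"]),
        k=int(doc["k"]),
        n=int(doc["n"]),
        aic=float(doc["aic"]),
        bic=float(doc["bic"]),
        vcov=None if vcov is None else np.asarray(vcov, dtype=float),
        converged=bool(doc["converged"]),
        iterations=int(doc.get("iterations", 0)),
        separation=tuple(doc.get("separation", ())),
        seed=doc.get("seed"),
    )


def load_config(source: str | Path | IO[str]) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParseError("configuration must be a mapping")
    return cfg
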