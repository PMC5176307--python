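"""Data model and I/O for surveillance text corpora.

A corpus is the unit a surveillance site works with for one surveillance
year: one record per child, each carrying the free-text developmental
evaluations abstracted from school and health sources, the clinician-assigned
case status (for years where clinician review happened), and the
demographic / prior-diagnosis metadata used in concordance profiling.

On disk a corpus is JSON lines (UTF-8, LF): line 1 is a header
``{"schema_version": ..., "surveillance_year": ...}``, every subsequent line
one child record with nested evaluations.  Writing is canonical (sorted
keys), so a given corpus always serializes to identical bytes.  A two-file
CSV dialect (children.csv + evaluations.csv joined on child_id) is supported
for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

SCHEMA_VERSION = "1.0"

Source = Literal["school", "health"]
Status = Literal["case", "noncase", "unknown"]
Sex = Literal["male", "female"]
RaceEth = Literal["white_nh", "black_nh", "hispanic", "other"]


class CorpusValidationError(ValueError):
    """Raised when a corpus file violates the schema or an invariant."""


class EvaluationRecord(BaseModel):
    """One abstracted developmental evaluation for one child."""

    child_id: str
    source: Source
    age_months: int = Field(ge=0)
    text: str

    @field_validator("text")
    @classmethod
    def _nonempty_text(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("evaluation text must be non-empty")
        return v


class ChildRecord(BaseModel):
    """One surveilled child: the unit of classification."""

    child_id: str
    status: Status = "unknown"
    evaluations: list[EvaluationRecord] = Field(min_length=1)
    sex: Sex = "male"
    race_eth: RaceEth = "other"
    iq_le_70: Optional[bool] = None
    prior_asd_dx: bool = False
    prior_asd_sped: bool = False
    secondary_review: Optional[bool] = None

    @model_validator(mode="after")
    def _evaluations_belong_to_child(self) -> "ChildRecord":
        for ev in self.evaluations:
            if ev.child_id != self.child_id:
                raise ValueError(
                    f"evaluation child_id {ev.child_id!r} does not match "
                    f"child {self.child_id!r}"
                )
        return self

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(ev.source for ev in self.evaluations)

    @property
    def age_first_eval(self) -> int:
        return min(ev.age_months for ev in self.evaluations)


class Corpus(BaseModel):
    """A surveillance year's worth of child records."""

    surveillance_year: int
    children: list[ChildRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_ids(self) -> "Corpus":
        seen: set[str] = set()
        for child in self.children:
            if child.child_id in seen:
                raise ValueError(f"duplicate child_id {child.child_id!r}")
            seen.add(child.child_id)
        return self

    @property
    def n_children(self) -> int:
        return len(self.children)

    @property
    def n_evaluations(self) -> int:
        return sum(c.n_evaluations for c in self.children)

    @property
    def n_case(self) -> int:
        return sum(c.status == "case" for c in self.children)

    @property
    def n_noncase(self) -> int:
        return sum(c.status == "noncase" for c in self.children)

    @property
    def n_unknown(self) -> int:
        return sum(c.status == "unknown" for c in self.children)

    @property
    def child_ids(self) -> list[str]:
        return [c.child_id for c in self.children]

    def statuses(self) -> dict[str, str]:
        return {c.child_id: c.status for c in self.children}

    def __getitem__(self, child_id: str) -> ChildRecord:
        for c in self.children:
            if c.child_id == child_id:
                return c
        raise KeyError(child_id)


def aggregate_child_text(child: ChildRecord) -> str:
    """Concatenate a child's evaluations into one classification document.

    Evaluations are joined with a single space in a deterministic order:
    ascending age at evaluation, ties broken by source name then input
    order.  Word order is irrelevant to the bag-of-words features, but a
    canonical order keeps serialized artifacts byte-reproducible.
    """
    if not child.evaluations:
        raise ValueError(f"child {child.child_id!r} has no evaluations")
    indexed = sorted(
        enumerate(child.evaluations),
        key=lambda t: (t[1].age_months, t[1].source, t[0]),
    )
    return " ".join(ev.text for _, ev in indexed)


def read_corpus(path: str | Path) -> Corpus:
    """Read and validate a JSON-lines corpus file.

    Malformed lines are reported with their 1-based line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CorpusValidationError(f"{path}: empty file (missing header)")
    try:
        header = json.loads(lines[0])
        year = int(header["surveillance_year"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise CorpusValidationError(f"{path}:1: invalid corpus header: {exc}")
    children = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            children.append(ChildRecord.model_validate_json(raw))
        except Exception as exc:
            raise CorpusValidationError(
                f"{path}:{lineno}: invalid child record: {exc}"
            ) from exc
    try:
        return Corpus(surveillance_year=year, children=children)
    except Exception as exc:
        raise CorpusValidationError(f"{path}: {exc}") from exc


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as canonical JSON lines (byte-stable for a fixed corpus)."""
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "surveillance_year": corpus.surveillance_year,
    }
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps(header, sort_keys=True, ensure_ascii=False))
        fh.write("\n")
        for child in corpus.children:
            fh.write(
                json.dumps(
                    child.model_dump(mode="json"),
                    sort_keys=True,
                    ensure_ascii=False,
                )
            )
            fh.write("\n")


def corpus_to_csv(corpus: Corpus, children_path: str | Path,
                  evaluations_path: str | Path) -> None:
    """Export the two-file CSV dialect (children.csv + evaluations.csv)."""
    child_rows = []
    eval_rows = []
    for c in corpus.children:
        d = c.model_dump(mode="json")
        d.pop("evaluations")
        child_rows.append(d)
        for ev in c.evaluations:
            eval_rows.append(ev.model_dump(mode="json"))
    pd.DataFrame(child_rows).to_csv(children_path, index=False)
    pd.DataFrame(eval_rows).to_csv(evaluations_path, index=False)


def corpus_from_csv(children_path: str | Path, evaluations_path: str | Path,
                    surveillance_year: int) -> Corpus:
    """Build a corpus from the two-file CSV dialect, joining on child_id."""
    kids = pd.read_csv(children_path, dtype={"child_id": str})
    evals = pd.read_csv(evaluations_path, dtype={"child_id": str})
    by_child: dict[str, list[EvaluationRecord]] = {}
    for rec in evals.to_dict("records"):
        ev = EvaluationRecord(
            child_id=rec["child_id"], source=rec["source"],
            age_months=int(rec["age_months"]), text=str(rec["text"]),
        )
        by_child.setdefault(ev.child_id, []).append(ev)
    children = []
    for rec in kids.to_dict("records"):
        cid = rec["child_id"]
        if cid not in by_child:
            raise CorpusValidationError(
                f"child {cid!r} has no evaluations in {evaluations_path}"
            )
        children.append(
            ChildRecord(
                child_id=cid,
                status=rec.get("status", "unknown"),
                evaluations=by_child[cid],
                sex=rec.get("sex", "male"),
                race_eth=rec.get("race_eth", "other"),
                iq_le_70=_opt_bool(rec.get("iq_le_70")),
                prior_asd_dx=bool(rec.get("prior_asd_dx", False)),
                prior_asd_sped=bool(rec.get("prior_asd_sped", False)),
                secondary_review=_opt_bool(rec.get("secondary_review")),
            )
        )
    return Corpus(surveillance_year=surveillance_year, children=children)


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return bool(v)


def require_labeled(corpus: Corpus, context: str = "training") -> None:
    """Raise if any child carries status 'unknown' (labels required)."""
    bad = [c.child_id for c in corpus.children if c.status == "unknown"]
    if bad:
        shown = ", ".join(bad[:10]) + ("..." if len(bad) > 10 else "")
        raise ValueError(
            f"{context} requires clinician labels for every child; "
            f"{len(bad)} children have status 'unknown': {shown}"
        )
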