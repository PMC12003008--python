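"""Labeled call-sequence corpora: data model, TSV I/O, validation, stratification.

A corpus holds alarm-call sequences over a small call alphabet (by default the
two olive colobus call types, low-pitched short ``A`` and high-pitched long
``B``), each labeled with the class of eliciting disturbance (eagle ``E``,
leopard ``L``, falling tree ``T``) and optional trial covariates such as
group, dataset, year, detection modality, or location.

The unit of analysis is the *sequence*, not the trial: one trial may
contribute several sequences, and trials that elicited no vocal response are
not representable here and must be excluded upstream.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "DEFAULT_CALL_ALPHABET",
    "DEFAULT_CLASS_ALPHABET",
    "COVARIATE_COLUMNS",
    "CorpusError",
    "CorpusFormatError",
    "CorpusValidationError",
    "CallSequence",
    "Corpus",
    "ValidationReport",
    "parse_tokens",
    "format_tokens",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
    "stratify_corpus",
]

DEFAULT_CALL_ALPHABET: tuple[str, ...] = ("A", "B")
DEFAULT_CLASS_ALPHABET: tuple[str, ...] = ("E", "L", "T")

#: Covariate columns recognized in the TSV format, in canonical output order.
COVARIATE_COLUMNS: tuple[str, ...] = ("group", "dataset", "year", "modality", "location")


class CorpusError(Exception):
    """Base class for corpus-related failures."""


class CorpusFormatError(CorpusError):
    """The input file does not have the expected tabular structure."""


class CorpusValidationError(CorpusError):
    """The data violate a corpus invariant (bad symbol, label, or empty row)."""


@dataclass(frozen=True)
class CallSequence:
    """One call sequence: an ordered tuple of call symbols plus its stimulus label.

    Parameters
    ----------
    tokens
        Non-empty ordered call symbols, e.g. ``("B", "A", "A")``.
    label
        Stimulus class that elicited the sequence, e.g. ``"T"``.
    covariates
        Optional trial covariates (group, dataset, year, modality, location).
    """

    tokens: tuple[str, ...]
    label: str
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "covariates", dict(self.covariates))

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """A collection of labeled call sequences with declared alphabets."""

    sequences: tuple[CallSequence, ...]
    call_alphabet: tuple[str, ...] = DEFAULT_CALL_ALPHABET
    class_alphabet: tuple[str, ...] = DEFAULT_CLASS_ALPHABET

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "call_alphabet", tuple(self.call_alphabet))
        object.__setattr__(self, "class_alphabet", tuple(self.class_alphabet))

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_classes(self) -> int:
        return len(self.class_alphabet)

    def class_counts(self) -> dict[str, int]:
        """Number of sequences per class, keyed in class-alphabet order."""
        counts = {y: 0 for y in self.class_alphabet}
        for seq in self.sequences:
            if seq.label in counts:
                counts[seq.label] += 1
        return counts

    def labels(self) -> list[str]:
        return [seq.label for seq in self.sequences]

    def max_length(self) -> int:
        return max((len(s) for s in self.sequences), default=0)

    def with_sequences(self, sequences: Iterable[CallSequence]) -> "Corpus":
        """A copy of this corpus holding ``sequences``; alphabets unchanged."""
        return dataclasses.replace(self, sequences=tuple(sequences))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_corpus`: ``ok`` iff ``issues`` is empty."""

    ok: bool
    issues: tuple[tuple[int, str], ...]


def parse_tokens(text: str, dialect: str = "auto") -> tuple[str, ...]:
    """Split a sequence cell into call tokens.

    ``dialect="compact"`` treats each character as one token (``"BAA"``),
    ``"delimited"`` splits on commas (``"B,A,A"``), and ``"auto"`` picks the
    delimited form whenever a comma is present. The compact form assumes a
    single-character call alphabet.
    """
    text = text.strip()
    if dialect not in ("auto", "compact", "delimited"):
        raise ValueError(f"unknown token dialect: {dialect!r}")
    if dialect == "delimited" or (dialect == "auto" and "," in text):
        return tuple(tok.strip() for tok in text.split(",") if tok.strip())
    return tuple(text)


def format_tokens(tokens: Sequence[str]) -> str:
    """Inverse of :func:`parse_tokens`: compact if all tokens are single characters."""
    if all(len(tok) == 1 for tok in tokens):
        return "".join(tokens)
    return ",".join(tokens)


def _row_covariates(row: Mapping[str, object], covariate_cols: Sequence[str]) -> dict[str, str]:
    cov: dict[str, str] = {}
    for col in covariate_cols:
        val = row[col]
        if val is None or (isinstance(val, float) and pd.isna(val)):
            continue
        text = str(val).strip()
        if text:
            cov[col] = text
    return cov


def read_corpus(
    path: str | Path,
    dialect: str = "auto",
    call_alphabet: Sequence[str] | None = None,
    class_alphabet: Sequence[str] | None = None,
) -> Corpus:
    """Read a corpus from a UTF-8 TSV with header columns ``sequence`` and ``label``.

    Any further columns are kept as per-sequence covariates. Alphabets are
    inferred from the data (sorted) unless declared; when declared, a symbol
    or label outside the alphabet raises :class:`CorpusValidationError`
    naming the offending data row (0-based).
    """
    path = Path(path)
    if not path.exists():
        raise CorpusFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in ("sequence", "label"):
        if col not in df.columns:
            raise CorpusFormatError(f"missing required column {col!r} in {path}")
    covariate_cols = [c for c in df.columns if c not in ("sequence", "label")]

    sequences: list[CallSequence] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        raw_seq, raw_label = row["sequence"], row["label"]
        if raw_seq is None or (isinstance(raw_seq, float) and pd.isna(raw_seq)):
            raise CorpusValidationError(f"row {i}: empty sequence")
        if raw_label is None or (isinstance(raw_label, float) and pd.isna(raw_label)):
            raise CorpusValidationError(f"row {i}: missing label")
        tokens = parse_tokens(str(raw_seq), dialect=dialect)
        label = str(raw_label).strip()
        if not tokens:
            raise CorpusValidationError(f"row {i}: empty sequence")
        if call_alphabet is not None:
            bad = [tok for tok in tokens if tok not in call_alphabet]
            if bad:
                raise CorpusValidationError(
                    f"row {i}: symbol(s) {bad} outside declared call alphabet {tuple(call_alphabet)}"
                )
        if class_alphabet is not None and label not in class_alphabet:
            raise CorpusValidationError(
                f"row {i}: label {label!r} outside declared class alphabet {tuple(class_alphabet)}"
            )
        sequences.append(CallSequence(tokens, label, _row_covariates(row, covariate_cols)))

    if call_alphabet is None:
        call_alphabet = tuple(sorted({tok for s in sequences for tok in s.tokens}))
    if class_alphabet is None:
        class_alphabet = tuple(sorted({s.label for s in sequences}))
    return Corpus(tuple(sequences), tuple(call_alphabet), tuple(class_alphabet))


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus to TSV; inverse of :func:`read_corpus` up to column order."""
    path = Path(path)
    seen: list[str] = []
    for seq in corpus.sequences:
        for name in seq.covariates:
            if name not in seen:
                seen.append(name)
    # canonical covariates first, then any extras in first-seen order
    cov_cols = [c for c in COVARIATE_COLUMNS if c in seen]
    cov_cols += [c for c in seen if c not in cov_cols]

    records = []
    for seq in corpus.sequences:
        rec: dict[str, str] = {"sequence": format_tokens(seq.tokens), "label": seq.label}
        for col in cov_cols:
            rec[col] = seq.covariates.get(col, "")
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=["sequence", "label", *cov_cols])
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:  # pragma: no cover - passthrough
        raise CorpusError(f"cannot write corpus to {path}: {exc}") from exc
    return path


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Check corpus invariants; issues are reported, never raised.

    Reported issues: empty token lists, symbols outside the call alphabet,
    labels outside the class alphabet, and declared classes with zero
    sequences (which make inverse-frequency weights undefined). Empty-class
    issues carry row index -1 since they are corpus-level.
    """
    issues: list[tuple[int, str]] = []
    call_set = set(corpus.call_alphabet)
    class_set = set(corpus.class_alphabet)
    for i, seq in enumerate(corpus.sequences):
        if len(seq.tokens) == 0:
            issues.append((i, "empty sequence"))
        bad = sorted({tok for tok in seq.tokens if tok not in call_set})
        if bad:
            issues.append((i, f"unknown symbol(s) {bad}"))
        if seq.label not in class_set:
            issues.append((i, f"unknown label {seq.label!r}"))
    counts = corpus.class_counts()
    for y in corpus.class_alphabet:
        if counts[y] == 0:
            issues.append((-1, f"empty class {y}"))
    return ValidationReport(ok=not issues, issues=tuple(issues))


def stratify_corpus(corpus: Corpus, covariate: str, value: str) -> Corpus:
    """Sub-corpus of sequences whose ``covariate`` equals ``value``.

    The class alphabet is kept, so downstream weight computation will refuse
    strata in which a class becomes empty. Raises :class:`CorpusError` if any
    sequence lacks the covariate.
    """
    missing = [i for i, s in enumerate(corpus.sequences) if covariate not in s.covariates]
    if missing:
        raise CorpusError(
            f"covariate {covariate!r} missing on {len(missing)} sequence(s), first at row {missing[0]}"
        )
    kept = [s for s in corpus.sequences if s.covariates[covariate] == value]
    return corpus.with_sequences(kept)
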