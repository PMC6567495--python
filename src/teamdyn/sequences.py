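"""Coded interaction event logs and their symbolic encoding.

A session of a small group (3–5 members) is coded upstream as a list of
events: at each time point one member addresses another member or the whole
team, with the behaviour classified into one of Bales' twelve Interaction
Process Analysis (IPA) categories.  This module ingests such event logs,
encodes who-interacts-with-whom as an ordered categorical symbol sequence
(the input to recurrence quantification), and quantifies agreement between
two coders with the two-way random-effects intraclass correlation.

Symbols: the unordered dyad {a, b} (a < b) becomes ``"a-b"``; member a
addressing the whole team becomes ``"a-T"``.  The full alphabet of an
m-member group has C(m, 2) dyad symbols plus m member-team symbols.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

TEAM = "TEAM"

EVENT_LOG_COLUMNS = ["time_s", "source", "target", "ipa_category", "coder"]


class EventLogError(ValueError):
    """Malformed event-log content; the message names the offending line."""


@dataclass(frozen=True)
class InteractionEvent:
    """One coded behaviour: who addressed whom, when, classified how."""

    time_s: float
    source: int
    target: int | str  # member id or the TEAM sentinel
    ipa_category: int
    coder: str = "1"

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"time_s must be >= 0, got {self.time_s}")
        if not 1 <= self.ipa_category <= 12:
            raise ValueError(f"ipa_category must be in 1..12, got {self.ipa_category}")
        if self.target != TEAM and self.source == self.target:
            raise ValueError(f"source and target coincide: {self.source}")


@dataclass(frozen=True)
class SymbolSequence:
    """Ordered categorical symbols for one group session."""

    symbols: tuple[str, ...]
    alphabet: frozenset[str]
    group_id: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("sequence must contain at least one symbol")
        stray = set(self.symbols) - set(self.alphabet)
        if stray:
            raise ValueError(f"symbols outside declared alphabet: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    n_subjects: int
    n_raters: int
    model_label: str = "two-way random, single measures, absolute agreement"


def read_event_log(path) -> list[InteractionEvent]:
    """Parse an event-log CSV (header ``time_s,source,target,ipa_category,coder``).

    Rows are returned in file order; a ``target`` of ``TEAM`` maps to the
    member-team sentinel.  Malformed rows raise :class:`EventLogError`
    naming the 1-based line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != EVENT_LOG_COLUMNS:
            raise EventLogError(
                f"{path}: expected header {','.join(EVENT_LOG_COLUMNS)}, got {reader.fieldnames}"
            )
        events: list[InteractionEvent] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                target_raw = row["target"].strip()
                target = TEAM if target_raw == TEAM else int(target_raw)
                event = InteractionEvent(
                    time_s=float(row["time_s"]),
                    source=int(row["source"]),
                    target=target,
                    ipa_category=int(row["ipa_category"]),
                    coder=row["coder"].strip(),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise EventLogError(f"{path}, line {lineno}: {exc}") from exc
            events.append(event)
    return events


def write_event_log(events: Iterable[InteractionEvent], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_LOG_COLUMNS)
        for ev in events:
            writer.writerow([f"{ev.time_s:g}", ev.source, ev.target, ev.ipa_category, ev.coder])


def dyad_alphabet(n_members: int) -> frozenset[str]:
    """All C(m,2) unordered dyad symbols plus the m member-team symbols."""
    if n_members < 2:
        raise ValueError("need at least 2 members")
    symbols = {f"{a}-{b}" for a in range(1, n_members + 1) for b in range(a + 1, n_members + 1)}
    symbols |= {f"{a}-T" for a in range(1, n_members + 1)}
    return frozenset(symbols)


def encode_sequence(
    events: Sequence[InteractionEvent],
    n_members: int,
    group_id: str = "",
    directed: bool = False,
) -> SymbolSequence:
    """Encode time-ordered events as a who-with-whom symbol sequence.

    Dyads are unordered by default — the events (1 -> 2) and (2 -> 1) map to
    the same symbol ``"1-2"``.  Set ``directed=True`` to keep direction
    (symbol ``"a>b"``).  Events with equal time stamps keep their input
    order.  The alphabet always covers every possible symbol for the group
    size, not just the observed ones.
    """
    if not events:
        raise ValueError("cannot encode an empty event list")
    events = sorted(events, key=lambda ev: ev.time_s)  # stable: ties keep file order
    symbols: list[str] = []
    for ev in events:
        if not 1 <= ev.source <= n_members:
            raise ValueError(f"source member id {ev.source} outside 1..{n_members}")
        if ev.target == TEAM:
            symbols.append(f"{ev.source}-T")
            continue
        if not 1 <= ev.target <= n_members:
            raise ValueError(f"target member id {ev.target} outside 1..{n_members}")
        if directed:
            symbols.append(f"{ev.source}>{ev.target}")
        else:
            a, b = sorted((ev.source, ev.target))
            symbols.append(f"{a}-{b}")
    if directed:
        alphabet = frozenset(
            {f"{a}>{b}" for a in range(1, n_members + 1) for b in range(1, n_members + 1) if a != b}
            | {f"{a}-T" for a in range(1, n_members + 1)}
        )
    else:
        alphabet = dyad_alphabet(n_members)
    return SymbolSequence(symbols=tuple(symbols), alphabet=alphabet, group_id=group_id)


def write_sequence(seq: SymbolSequence, path) -> None:
    """One symbol per line, preceded by a ``# alphabet:`` header comment."""
    with Path(path).open("w") as fh:
        fh.write(f"# group: {seq.group_id}\n")
        fh.write(f"# alphabet: {','.join(sorted(seq.alphabet))}\n")
        for sym in seq.symbols:
            fh.write(sym + "\n")


def read_sequence(path) -> SymbolSequence:
    path = Path(path)
    group_id = path.stem
    alphabet: frozenset[str] | None = None
    symbols: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("alphabet:"):
                    alphabet = frozenset(s.strip() for s in body[len("alphabet:"):].split(","))
                elif body.startswith("group:"):
                    group_id = body[len("group:"):].strip() or group_id
                continue
            symbols.append(line)
    if alphabet is None:
        alphabet = frozenset(symbols)
    return SymbolSequence(symbols=tuple(symbols), alphabet=alphabet, group_id=group_id)


def icc_two_way_random(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, single measures, absolute agreement.

    From the two-way ANOVA decomposition of a subjects x raters matrix:

        ICC = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)

    with BMS the between-subjects, JMS the between-raters and EMS the
    residual mean square, for n subjects and k raters.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix contains missing cells")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("constant ratings matrix: ICC undefined (zero variance)")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    icc = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    return ICCResult(icc=float(icc), n_subjects=n, n_raters=k)


def ipa_category_frequencies(events: Iterable[InteractionEvent]) -> dict[int, int]:
    """Count events per IPA category 1..12 (retained for export; the RQA
    alphabet is who-with-whom only)."""
    freqs = {c: 0 for c in range(1, 13)}
    for ev in events:
        freqs[ev.ipa_category] += 1
    return freqs
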