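"""Stable accessions for consortium metadata.

An accession is an identifier of the form ``ENC`` + a two-letter entity-type
code + three decimal digits + three uppercase letters, e.g. ``ENCSR000DVI``
for an experiment. The six type codes map to fixed entity categories:

=====  =================
code   entity category
=====  =================
SR     experiment
BS     biosample
DO     donor / strain
AB     antibody lot
LB     library
FF     file
=====  =================

Accessions are stable: once issued (even to a record later deleted) a serial
is never re-issued. The registry therefore keeps an append-only set of issued
serials per type code, persistable as a plain-text ledger. Newer files that
replace older ones keep their own accession and are *related* to the file
they supersede; the registry tracks those supersession edges and rejects
self-reference and cycles.

Minting picks serials pseudo-randomly (seeded, without replacement) rather
than sequentially, so accession text leaks nothing about submission order.
"""

from __future__ import annotations

import random
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    AccessionExhaustedError,
    MalformedAccessionError,
    SupersessionError,
)

#: fixed type-code -> entity-category mapping
TYPE_CODES = {
    "SR": "experiment",
    "BS": "biosample",
    "DO": "donor",
    "AB": "antibody_lot",
    "LB": "library",
    "FF": "file",
}

#: record type_name -> accession type code (types without a code use local ids)
TYPE_NAME_TO_CODE = {
    "experiment": "SR",
    "biosample": "BS",
    "donor": "DO",
    "antibody_lot": "AB",
    "library": "LB",
    "file": "FF",
}

PREFIX = "ENC"


@dataclass(frozen=True)
class AccessionGrammar:
    """Shape of the serial tail: ``n_digits`` decimal digits followed by
    ``n_letters`` uppercase letters. The production grammar is 3+3; reduced
    grammars exist so exhaustion and capacity are testable by enumeration."""

    n_digits: int = 3
    n_letters: int = 3

    @property
    def serial_length(self) -> int:
        return self.n_digits + self.n_letters

    def capacity(self) -> int:
        """Number of distinct serials: 10^digits * 26^letters."""
        return 10**self.n_digits * 26**self.n_letters

    def serial_at(self, index: int) -> str:
        """Bijective index -> serial mapping (digits major, letters minor)."""
        n_letter_combos = 26**self.n_letters
        if not 0 <= index < self.capacity():
            raise IndexError(index)
        digit_part, letter_part = divmod(index, n_letter_combos)
        digits = str(digit_part).zfill(self.n_digits)
        letters = ""
        for _ in range(self.n_letters):
            letter_part, rem = divmod(letter_part, 26)
            letters = string.ascii_uppercase[rem] + letters
        return digits + letters

    def matches_serial(self, serial: str) -> bool:
        return bool(
            re.fullmatch(
                rf"[0-9]{{{self.n_digits}}}[A-Z]{{{self.n_letters}}}", serial
            )
        )


GRAMMAR = AccessionGrammar()  # the production 3-digit + 3-letter grammar


@dataclass(frozen=True)
class Accession:
    """A parsed accession: full text, entity-type code and serial tail."""

    text: str
    type_code: str
    serial: str

    @property
    def category(self) -> str:
        return TYPE_CODES[self.type_code]

    def __str__(self) -> str:
        return self.text


def parse_accession(text: str, grammar: AccessionGrammar = GRAMMAR) -> Accession:
    """Parse accession ``text``, rejecting anything outside the grammar.

    The error names the first failing constraint (length, case, prefix,
    type-code, digits, letters) to make submission mistakes diagnosable.
    """
    if not isinstance(text, str):
        raise MalformedAccessionError(repr(text), "type", "accession must be text")
    expected_len = len(PREFIX) + 2 + grammar.serial_length
    if len(text) != expected_len:
        raise MalformedAccessionError(
            text, "length", f"expected {expected_len} characters, got {len(text)}"
        )
    if text != text.upper():
        raise MalformedAccessionError(text, "case", "accessions are uppercase only")
    if not text.startswith(PREFIX):
        raise MalformedAccessionError(text, "prefix", f"must start with {PREFIX!r}")
    code = text[len(PREFIX) : len(PREFIX) + 2]
    if code not in TYPE_CODES:
        raise MalformedAccessionError(
            text, "type-code", f"unknown entity type code {code!r}"
        )
    serial = text[len(PREFIX) + 2 :]
    digits, letters = serial[: grammar.n_digits], serial[grammar.n_digits :]
    if not re.fullmatch(rf"[0-9]{{{grammar.n_digits}}}", digits):
        raise MalformedAccessionError(
            text, "digits", f"serial must start with {grammar.n_digits} decimal digits"
        )
    if not re.fullmatch(rf"[A-Z]{{{grammar.n_letters}}}", letters):
        raise MalformedAccessionError(
            text, "letters", f"serial must end with {grammar.n_letters} uppercase letters"
        )
    return Accession(text=text, type_code=code, serial=serial)


def is_accession(text: str, grammar: AccessionGrammar = GRAMMAR) -> bool:
    try:
        parse_accession(text, grammar)
        return True
    except MalformedAccessionError:
        return False


def capacity(type_code: str, grammar: AccessionGrammar = GRAMMAR) -> int:
    """Distinct accessions available for one entity type code."""
    if type_code not in TYPE_CODES:
        raise MalformedAccessionError(type_code, "type-code", "unknown entity type code")
    return grammar.capacity()


@dataclass
class AccessionRegistry:
    """Append-only record of issued serials plus file supersession edges.

    ``issued`` never shrinks: deleting a record does not free its accession.
    ``supersessions`` maps new file accession -> the accession it replaces.
    """

    grammar: AccessionGrammar = field(default_factory=AccessionGrammar)
    issued: dict[str, set[str]] = field(
        default_factory=lambda: {code: set() for code in TYPE_CODES}
    )
    supersessions: dict[str, str] = field(default_factory=dict)

    # -- minting ----------------------------------------------------------

    def mint(self, type_code: str, rng: random.Random) -> Accession:
        if type_code not in TYPE_CODES:
            raise MalformedAccessionError(
                type_code, "type-code", "unknown entity type code"
            )
        taken = self.issued[type_code]
        cap = self.grammar.capacity()
        if len(taken) >= cap:
            raise AccessionExhaustedError(
                f"all {cap} serials issued for type code {type_code}"
            )
        # Rejection sampling is fast while the space is sparse; fall back to
        # choosing among the enumerated remainder as it fills up.
        serial = None
        for _ in range(64):
            candidate = self.grammar.serial_at(rng.randrange(cap))
            if candidate not in taken:
                serial = candidate
                break
        if serial is None:
            remaining = sorted(
                set(self.grammar.serial_at(i) for i in range(cap)) - taken
            )
            serial = rng.choice(remaining)
        taken.add(serial)
        return Accession(text=f"{PREFIX}{type_code}{serial}", type_code=type_code, serial=serial)

    # -- supersession ------------------------------------------------------

    def supersede_file(self, old: Accession | str, new: Accession | str) -> tuple[str, str]:
        """Record that file ``new`` replaces file ``old``; returns the edge."""
        old_acc = old if isinstance(old, Accession) else parse_accession(old, self.grammar)
        new_acc = new if isinstance(new, Accession) else parse_accession(new, self.grammar)
        for acc in (old_acc, new_acc):
            if acc.type_code != "FF":
                raise SupersessionError(
                    f"{acc.text} is a {acc.category} accession; only files supersede files"
                )
        if old_acc.text == new_acc.text:
            raise SupersessionError(f"{new_acc.text} cannot supersede itself")
        if old_acc.text in {v for v in self.supersessions.values()}:
            raise SupersessionError(f"{old_acc.text} is already superseded")
        # walking old's chain must not lead back to new
        for node in self.supersession_chain(old_acc.text):
            if node == new_acc.text:
                raise SupersessionError(
                    f"superseding {old_acc.text} by {new_acc.text} would create a cycle"
                )
        self.supersessions[new_acc.text] = old_acc.text
        return (new_acc.text, old_acc.text)

    def supersession_chain(self, accession_text: str) -> list[str]:
        """Accessions superseded, directly or transitively, by ``accession_text``."""
        chain = []
        node = accession_text
        while node in self.supersessions:
            node = self.supersessions[node]
            if node in chain or node == accession_text:  # defensive; inserts forbid this
                raise SupersessionError(f"cycle in supersession chain at {node}")
            chain.append(node)
        return chain

    # -- persistence -------------------------------------------------------

    def save_ledger(self, path: str | Path) -> None:
        """One issued accession per line; supersessions as 'NEW > OLD'."""
        lines = ["# metaforge accession ledger"]
        for code in sorted(self.issued):
            for serial in sorted(self.issued[code]):
                lines.append(f"{PREFIX}{code}{serial}")
        for new, old in sorted(self.supersessions.items()):
            lines.append(f"{new} > {old}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load_ledger(
        cls, path: str | Path, grammar: AccessionGrammar = GRAMMAR
    ) -> "AccessionRegistry":
        registry = cls(grammar=grammar)
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ">" in line:
                new, old = (part.strip() for part in line.split(">", 1))
                registry.supersessions[new] = old
                continue
            acc = parse_accession(line, grammar)
            registry.issued[acc.type_code].add(acc.serial)
        return registry


def mint_accession(registry: AccessionRegistry, type_code: str, seed: int) -> Accession:
    """Mint one accession reproducibly from (registry state, seed)."""
    return registry.mint(type_code, random.Random(seed))
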