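"""Reading and writing profile HMMs in the HMMER3 ASCII format.

Only the ``HMMER3/f`` dialect is handled: a text header, a ``HMM`` table of
match/insert emissions and node transitions stored as negative natural-log
probabilities (``*`` encodes probability zero), and a ``//`` terminator per
profile.  Files written by ``hmmbuild`` can be read (statistics and cutoff
header lines are preserved where needed and otherwise skipped), and files
written here are readable by HMMER and pyhmmer.

Because values are printed with five decimals, probabilities survive a
round trip only to about 1e-5 relative accuracy; a second write of a
re-read profile is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

from .alphabet import AMINO_ACIDS, BACKGROUND
from .profile_hmm import ProfileHMM

_DATE = "Thu Jan  1 00:00:00 1970"  # fixed so writes are reproducible


class Hmmer3FormatError(ValueError):
    """Raised on malformed HMMER3 input, naming the offending line."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _fmt(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.5f}"


def _parse(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise Hmmer3FormatError(lineno, f"expected a score field, got {tok!r}")


def write_hmmer3(hmms: Iterable[ProfileHMM] | ProfileHMM, path: str | Path) -> None:
    """Write one or more profiles to a HMMER3 ASCII file."""
    if isinstance(hmms, ProfileHMM):
        hmms = [hmms]
    with open(path, "w") as fh:
        for hmm in hmms:
            _write_one(hmm, fh)


def _write_one(hmm: ProfileHMM, fh: TextIO) -> None:
    L = hmm.L
    fh.write("HMMER3/f [rbpdetect | profile file]\n")
    fh.write(f"NAME  {hmm.name}\n")
    fh.write(f"LENG  {L}\n")
    fh.write("ALPH  amino\n")
    fh.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   yes\n")
    fh.write(f"DATE  {_DATE}\n")
    fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
    fh.write(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
    )
    compo = "  ".join(f"{_fmt(p):>7s}" for p in hmm.background)
    fh.write(f"  COMPO   {compo}\n")
    ins0 = "  ".join(f"{_fmt(p):>7s}" for p in hmm.insert_emissions[0])
    fh.write(f"          {ins0}\n")
    t0 = "  ".join(f"{_fmt(p):>7s}" for p in hmm.transitions[0])
    fh.write(f"          {t0}\n")
    for k in range(1, L + 1):
        row = hmm.match_emissions[k - 1]
        cons_idx = int(row.argmax())
        cons = AMINO_ACIDS[cons_idx]
        cons = cons.upper() if row[cons_idx] > 0.5 else cons.lower()
        em = "  ".join(f"{_fmt(p):>7s}" for p in row)
        fh.write(f"{k:>7d}   {em}{k:>7d} {cons} - - -\n")
        ins = "  ".join(f"{_fmt(p):>7s}" for p in hmm.insert_emissions[k])
        fh.write(f"          {ins}\n")
        tr = "  ".join(f"{_fmt(p):>7s}" for p in hmm.transitions[k])
        fh.write(f"          {tr}\n")
    fh.write("//\n")


def read_hmmer3(path: str | Path) -> list[ProfileHMM]:
    """Parse every profile in a HMMER3 ASCII file.

    Raises :class:`Hmmer3FormatError` on malformed headers, truncated
    matrices, or a missing ``//`` terminator.
    """
    lines = Path(path).read_text().splitlines()
    hmms: list[ProfileHMM] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        hmm, i = _read_one(lines, i)
        hmms.append(hmm)
    if not hmms:
        raise Hmmer3FormatError(1, "file contains no profiles")
    return hmms


def _read_one(lines: list[str], i: int) -> tuple[ProfileHMM, int]:
    if not lines[i].startswith("HMMER3/f"):
        raise Hmmer3FormatError(i + 1, "expected a HMMER3/f header")
    i += 1
    name = None
    L = None
    while i < len(lines) and not lines[i].startswith("HMM "):
        fields = lines[i].split(None, 1)
        if fields:
            key = fields[0]
            if key == "NAME":
                name = fields[1].strip() if len(fields) > 1 else ""
            elif key == "LENG":
                L = int(fields[1])
            elif key == "ALPH" and fields[1].strip().lower() != "amino":
                raise Hmmer3FormatError(i + 1, "only the amino alphabet is supported")
        i += 1
    if i >= len(lines):
        raise Hmmer3FormatError(len(lines), "missing HMM table header")
    if name is None or L is None:
        raise Hmmer3FormatError(i + 1, "header lacks NAME or LENG")
    i += 2  # skip the two HMM table header lines

    # optional COMPO line
    background = BACKGROUND.copy()
    if i < len(lines) and lines[i].split()[:1] == ["COMPO"]:
        toks = lines[i].split()[1:]
        if len(toks) != 20:
            raise Hmmer3FormatError(i + 1, "COMPO line must have 20 fields")
        background = np.array([_parse(t, i + 1) for t in toks])
        s = background.sum()
        if s > 0:
            background /= s
        i += 1

    insert_emissions = np.zeros((L + 1, 20))
    transitions = np.zeros((L + 1, 7))
    match_emissions = np.zeros((L, 20))

    insert_emissions[0] = _take(lines, i, 20, "node 0 insert emissions")
    i += 1
    transitions[0] = _take(lines, i, 7, "node 0 transitions")
    i += 1
    for k in range(1, L + 1):
        toks = lines[i].split() if i < len(lines) else []
        if len(toks) < 21 or toks[0] != str(k):
            raise Hmmer3FormatError(i + 1, f"expected match line for node {k}")
        match_emissions[k - 1] = [_parse(t, i + 1) for t in toks[1:21]]
        i += 1
        insert_emissions[k] = _take(lines, i, 20, f"node {k} insert emissions")
        i += 1
        transitions[k] = _take(lines, i, 7, f"node {k} transitions")
        i += 1
    if i >= len(lines) or lines[i].strip() != "//":
        raise Hmmer3FormatError(i + 1, "missing // terminator")
    i += 1

    # Probabilities are kept exactly as stored (quantised to the file's five
    # decimals of -ln p) so that write(read(f)) reproduces f byte for byte;
    # rows therefore sum to 1 only within the quantisation tolerance.
    # Structural convention for the delete state missing at node 0 and L:
    transitions[0, 5], transitions[0, 6] = 1.0, 0.0
    transitions[L, 5], transitions[L, 6] = 1.0, 0.0

    hmm = ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
    )
    return hmm, i


def _take(lines: list[str], i: int, count: int, what: str) -> list[float]:
    toks = lines[i].split() if i < len(lines) else []
    if len(toks) != count:
        raise Hmmer3FormatError(i + 1, f"expected {count} fields for {what}")
    return [_parse(t, i + 1) for t in toks]
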