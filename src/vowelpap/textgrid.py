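"""Minimal PRAAT TextGrid reader/writer.

Supports interval tiers in both the full ("ooTextFile" with ``key = value``
lines) and the short text format.  Point tiers are parsed and exposed but
nothing downstream uses them.  Multi-line interval texts are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: List[Tuple[float, float, str]]  # (xmin, xmax, text)


def _tokenize(lines: Sequence[str]) -> List[str]:
    """Reduce both TextGrid dialects to one value stream.

    Full-format lines are ``key = value`` — stripping up to the first ``=``
    yields exactly the short-format stream; structural lines (``item [1]:``,
    ``tiers? <exists>``) carry no value and are dropped.
    """
    tokens: List[str] = []
    for raw in lines:
        line = raw.strip()
        if not line or "<exists>" in line:
            continue
        if "=" in line:
            value = line.split("=", 1)[1].strip()
        elif line.endswith(":") or line.endswith("]:"):
            continue
        else:
            value = line
        if value:
            tokens.append(value)
    return tokens


def _unquote(token: str) -> str:
    token = token.strip()
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        token = token[1:-1]
    return token.replace('""', '"')


def read_textgrid(path: str | Path) -> List[IntervalTier]:
    """Read all interval tiers from a TextGrid file."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines or "ooTextFile" not in lines[0]:
        raise ValueError(f"{path}: not a PRAAT ooTextFile")
    tokens = _tokenize(lines[2:])  # drop the two header lines
    it = iter(tokens)

    def nextf() -> float:
        return float(next(it))

    def nexts() -> str:
        return _unquote(next(it))

    try:
        nextf()  # global xmin
        nextf()  # global xmax
        n_tiers = int(nextf())
        tiers: List[IntervalTier] = []
        for _ in range(n_tiers):
            klass = nexts()
            name = nexts()
            xmin = nextf()
            xmax = nextf()
            n = int(nextf())
            if klass == "IntervalTier":
                intervals = []
                for _ in range(n):
                    lo = nextf()
                    hi = nextf()
                    label = nexts()
                    intervals.append((lo, hi, label))
                tiers.append(IntervalTier(name=name, xmin=xmin, xmax=xmax,
                                          intervals=intervals))
            else:  # TextTier: (time, mark) pairs; parsed but not retained
                for _ in range(n):
                    nextf()
                    nexts()
    except StopIteration as exc:
        raise ValueError(f"{path}: truncated TextGrid") from exc
    return tiers


def write_textgrid(
    path: str | Path,
    tier_name: str,
    intervals: Sequence[Tuple[float, float, str]],
    xmax: float,
    xmin: float = 0.0,
) -> None:
    """Write one interval tier in the full TextGrid format, padding gaps
    between labelled intervals with empty-text intervals as PRAAT does."""
    filled: List[Tuple[float, float, str]] = []
    cursor = xmin
    for lo, hi, text in sorted(intervals, key=lambda t: t[0]):
        if lo > cursor:
            filled.append((cursor, lo, ""))
        filled.append((lo, hi, text))
        cursor = hi
    if cursor < xmax:
        filled.append((cursor, xmax, ""))

    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        f"        xmin = {xmin}",
        f"        xmax = {xmax}",
        f"        intervals: size = {len(filled)}",
    ]
    for i, (lo, hi, text) in enumerate(filled, start=1):
        out += [
            f"        intervals [{i}]:",
            f"            xmin = {lo}",
            f"            xmax = {hi}",
            f'            text = "{text}"',
        ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
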