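"""Minimal Praat TextGrid (long text format) reader/writer.

Only interval tiers are supported, which is all the segmentation workflow
needs.  Boundaries survive a write/read round trip to 1e-6 s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .tokens import Interval


class TextGridParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval]

    def validate(self) -> None:
        prev = self.xmin
        for iv in self.intervals:
            if iv.start < prev - 1e-9:
                raise TextGridParseError(
                    f"tier {self.name!r}: interval starting {iv.start:.6f}s "
                    f"overlaps previous boundary {prev:.6f}s")
            prev = iv.end
        if self.intervals and self.intervals[-1].end > self.xmax + 1e-9:
            raise TextGridParseError(
                f"tier {self.name!r}: last interval exceeds tier xmax")


def write_textgrid(tiers: list[IntervalTier], path: str) -> None:
    xmin = min(t.xmin for t in tiers)
    xmax = max(t.xmax for t in tiers)
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for i, tier in enumerate(tiers, start=1):
        tier.validate()
        lines += [
            f"    item [{i}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier.name}"',
            f"        xmin = {tier.xmin:.6f}",
            f"        xmax = {tier.xmax:.6f}",
            f"        intervals: size = {len(tier.intervals)}",
        ]
        for j, iv in enumerate(tier.intervals, start=1):
            lines += [
                f"        intervals [{j}]:",
                f"            xmin = {iv.start:.6f}",
                f"            xmax = {iv.end:.6f}",
                f'            text = "{iv.label}"',
            ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_KV = re.compile(r'^\s*(\S[^=]*?)\s*=\s*(.*?)\s*$')


def read_textgrid(path: str) -> list[IntervalTier]:
    """Parse a long-format TextGrid into interval tiers (with validation)."""
    with open(path) as fh:
        raw = fh.readlines()

    tiers: list[IntervalTier] = []
    tier: IntervalTier | None = None
    pending: dict = {}
    in_interval = False

    def finish_interval(line_no: int) -> None:
        nonlocal pending, in_interval
        if not in_interval:
            return
        try:
            tier.intervals.append(
                Interval(float(pending["xmin"]), float(pending["xmax"]),
                         pending.get("text", "")))
        except KeyError as exc:
            raise TextGridParseError(f"interval missing field {exc}", line_no)
        pending = {}
        in_interval = False

    for line_no, line in enumerate(raw, start=1):
        stripped = line.strip()
        if stripped.startswith("intervals ["):
            finish_interval(line_no)
            in_interval = True
            continue
        if stripped.startswith("item ["):
            finish_interval(line_no)
            if tier is not None:
                tier.validate()
                tiers.append(tier)
            tier = None
            continue
        m = _KV.match(stripped)
        if not m:
            continue
        key, value = m.group(1), m.group(2).strip('"')
        if key == "class":
            if value == "IntervalTier":
                tier = IntervalTier(name="", xmin=0.0, xmax=0.0, intervals=[])
            elif value == "TextGrid":
                continue
            elif tier is None and value != "ooTextFile":
                raise TextGridParseError(f"unsupported tier class {value!r}",
                                         line_no)
        elif tier is not None and not in_interval:
            if key == "name":
                tier.name = value
            elif key == "xmin":
                tier.xmin = float(value)
            elif key == "xmax":
                tier.xmax = float(value)
        elif in_interval and key in ("xmin", "xmax", "text"):
            pending[key] = value
    finish_interval(len(raw))
    if tier is not None:
        tier.validate()
        tiers.append(tier)
    if not tiers:
        raise TextGridParseError("no interval tiers found in file")
    return tiers


def segments_tier(token_intervals: list[Interval], duration: float,
                  name: str = "segments") -> IntervalTier:
    return IntervalTier(name=name, xmin=0.0, xmax=duration,
                        intervals=list(token_intervals))
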