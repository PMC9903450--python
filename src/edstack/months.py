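"""Calendar-month labels: "YYYY-MM" strings and simple arithmetic on them."""

from __future__ import annotations


def parse_month(label: str) -> tuple[int, int]:
    """Split a "YYYY-MM" label into (year, month). Raises ValueError on junk."""
    parts = str(label).split("-")
    if len(parts) != 2:
        raise ValueError(f"bad month label {label!r}; expected 'YYYY-MM'")
    year, month = int(parts[0]), int(parts[1])
    if not 1 <= month <= 12:
        raise ValueError(f"bad month label {label!r}; month out of range")
    return year, month


def month_label(year: int, month: int) -> str:
    return f"{year:04d}-{month:02d}"


def month_year(label: str) -> int:
    return parse_month(label)[0]


def calendar_month(label: str) -> int:
    return parse_month(label)[1]


def shift_month(label: str, k: int) -> str:
    """Label k calendar months after `label` (k may be negative)."""
    year, month = parse_month(label)
    idx = year * 12 + (month - 1) + k
    return month_label(idx // 12, idx % 12 + 1)


def month_range(start: str, n: int) -> list[str]:
    return [shift_month(start, k) for k in range(n)]
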