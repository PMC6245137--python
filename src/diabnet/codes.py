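"""ICD-9/ICD-10 code lists for the type-2-diabetes index condition and its six
tracked complications, plus the prefix-matching rule used everywhere codes are
compared.

Codes are treated as opaque dotted strings; a record code matches a list entry
when it starts with that entry ("I50.22" matches "I50", "584.9" matches "584").
No ICD-9 <-> ICD-10 equivalence mapping is attempted.
"""

from __future__ import annotations

from typing import Iterable

#: Inclusion codes for type 2 diabetes mellitus (index condition).
T2DM_CODES: tuple[str, ...] = (
    "249", "250", "357.2",
    "362.01", "362.02", "362.03", "362.04", "362.05", "362.06", "362.07",
    "366.41", "E10", "E11",
)

#: Diagnosis code prefixes defining each tracked complication.
COMPLICATION_CODES: dict[str, tuple[str, ...]] = {
    "kidney": (
        "584", "586", "585", "403", "404", "581", "583", "588",
        "N18", "N17", "N19", "I12", "I13", "N04", "N05", "N08", "N25", "593",
    ),
    "liver": ("571", "572", "573", "K76", "K75"),
    "heart_failure": ("428", "I50"),
    "myocardial_infarction": ("410", "412", "I21"),
    "stroke": ("435", "G45", "430", "431", "I60", "I61", "432", "I62",
               "436", "433", "434"),
    "retinopathy": ("362", "H35"),
}

COMPLICATIONS: tuple[str, ...] = tuple(COMPLICATION_CODES)

#: Threshold on glycated hemoglobin (%) that qualifies as an inclusion
#: criterion on its own.
HBA1C_THRESHOLD: float = 6.5


def matches_any(code: str, prefixes: Iterable[str]) -> bool:
    """True if ``code`` prefix-matches any entry of ``prefixes``.

    Raises ``ValueError`` for empty/non-string codes so malformed records are
    reported rather than silently skipped.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError(f"malformed diagnosis code: {code!r}")
    c = code.strip().upper()
    return any(c.startswith(p) for p in prefixes)


def is_t2dm_code(code: str) -> bool:
    """True if ``code`` is a type-2-diabetes inclusion code."""
    return matches_any(code, T2DM_CODES)


def complication_prefixes(complication: str) -> tuple[str, ...]:
    """Code-prefix list for one of the six complications; KeyError-safe."""
    try:
        return COMPLICATION_CODES[complication]
    except KeyError:
        raise ValueError(
            f"unknown complication {complication!r}; "
            f"expected one of {sorted(COMPLICATION_CODES)}"
        ) from None
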