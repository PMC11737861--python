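"""ACMG/AMP 2015 evidence codes and combining rules.

Evidence codes carry a category prefix encoding their strength —
pathogenic very strong (PVS), strong (PS), moderate (PM), supporting (PP)
and benign stand-alone (BA), strong (BS), supporting (BP). The combining
table aggregates a set of codes into one of five classifications; any
combination satisfying both a pathogenic and a benign rule, or neither,
is uncertain.
"""

from __future__ import annotations

import enum
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")

CATEGORIES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")


class Classification(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True, order=True)
class AcmgCode:
    """A single evidence code, e.g. PM2 (category PM, identifier 'PM2')."""

    identifier: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.identifier):
            raise ValueError(f"unknown evidence code {self.identifier!r}")

    @property
    def category(self) -> str:
        return _CODE_RE.match(self.identifier).group(1)


def _tally(codes: Iterable[AcmgCode]) -> Counter:
    # duplicate identifiers collapse: the same line of evidence counts once
    return Counter(code.category for code in set(codes))


def acmg_combine(codes: Sequence[AcmgCode]) -> Classification:
    """Apply the 2015 combining table to a set of evidence codes.

    Pathogenic requires (i) one very-strong code plus corroboration (one
    strong, two moderate, one moderate plus one supporting, or two
    supporting), (ii) two strong codes, or (iii) one strong code plus three
    moderate, two moderate with two supporting, or one moderate with four
    supporting. Likely pathogenic requires one very-strong or strong code
    with one moderate, one strong with two supporting, three moderate, two
    moderate with two supporting, or one moderate with four supporting.
    Benign requires a stand-alone code or two strong benign codes; likely
    benign one strong benign plus one supporting, or two supporting.
    Contradictory evidence (both pathogenic and benign rules met) and
    everything else is uncertain.
    """
    t = _tally(codes)
    pvs, ps, pm, pp = t["PVS"], t["PS"], t["PM"], t["PP"]
    ba, bs, bp = t["BA"], t["BS"], t["BP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return Classification.UNCERTAIN
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN


_PATHOGENIC_SIDE = {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC}


def simulate_upgrades(
    vus_codes: Mapping[str, Sequence[AcmgCode]], added: AcmgCode
) -> tuple[int, float]:
    """Count how many uncertain variants would reach (at least) likely
    pathogenic if one further evidence code were applied to each.

    Every input variant must currently classify as uncertain. Variants that
    already carry the added code are skipped with a warning and excluded
    from the denominator.
    """
    n_upgraded = 0
    n_eligible = 0
    for name, codes in vus_codes.items():
        if acmg_combine(list(codes)) is not Classification.UNCERTAIN:
            raise ValueError(f"variant {name!r} does not currently classify as uncertain")
        if added in set(codes):
            warnings.warn(f"variant {name!r} already carries {added.identifier}; skipped")
            continue
        n_eligible += 1
        if acmg_combine(list(codes) + [added]) in _PATHOGENIC_SIDE:
            n_upgraded += 1
    fraction = n_upgraded / n_eligible if n_eligible else 0.0
    return n_upgraded, fraction
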