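"""Rule-based selection of active components from the full chemical table.

Three screens are applied: Lipinski-style drug-likeness (five bounds, with a
deliberate mix of strict and inclusive inequalities), oral bioavailability
(OB >= 30% by default) and gastrointestinal absorption class (``high``
retained).  Experimentally validated high-concentration components bypass the
screens entirely.

A missing value never silently fails a rule: the affected rule is reported as
``None`` ("not applicable") and excluded from the combination, so compounds
from sources without OB predictions are not eliminated wholesale.  Components
with no usable ADMET data at all remain inactive unless validated, and are
counted separately in the log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .network import ComponentRecord

logger = logging.getLogger(__name__)

COMBINE_MODES = ("all-rules", "any-rule")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def lipinski_pass(
    mw: Optional[float],
    logp: Optional[float],
    hbd: Optional[int],
    hba: Optional[int],
    rotatable_bonds: Optional[int],
) -> Optional[bool]:
    """Drug-likeness verdict; ``None`` when any descriptor is missing.

    Passes iff hbd <= 5, hba < 10 (strict), mw <= 500, logP <= 5 and
    rotatable bonds < 10 (strict).
    """
    if any(_missing(x) for x in (mw, logp, hbd, hba, rotatable_bonds)):
        return None
    return hbd <= 5 and hba < 10 and mw <= 500 and logp <= 5 and rotatable_bonds < 10


@dataclass(frozen=True)
class AdmetVerdict:
    """Per-component screening outcome.

    ``active`` is the combined rule result OR the validated override;
    rule fields are ``None`` when not evaluable from the record.
    """

    component_id: str
    lipinski_pass: Optional[bool]
    ob_pass: Optional[bool]
    gi_pass: Optional[bool]
    validated: bool
    active: bool

    @property
    def all_rules_missing(self) -> bool:
        return self.lipinski_pass is None and self.ob_pass is None and self.gi_pass is None


def _combine(verdicts: Sequence[Optional[bool]], mode: str) -> bool:
    applicable = [v for v in verdicts if v is not None]
    if not applicable:
        return False
    if mode == "all-rules":
        return all(applicable)
    return any(applicable)


def select_active_components(
    records: Sequence[ComponentRecord],
    ob_threshold: float = 30.0,
    combine: str = "all-rules",
) -> list[AdmetVerdict]:
    """Screen components; validated records are active regardless of ADMET.

    Verdicts are computed independently per record.  ``combine`` chooses the
    conjunction (default) or disjunction of the applicable rules.
    """
    if combine not in COMBINE_MODES:
        raise ValueError(f"combine must be one of {COMBINE_MODES}, got {combine!r}")
    out: list[AdmetVerdict] = []
    n_active = n_missing_all = 0
    for r in records:
        lip = lipinski_pass(r.mw, r.logp, r.hbd, r.hba, r.rotatable_bonds)
        ob = None if _missing(r.ob_percent) else r.ob_percent >= ob_threshold
        gi = None if r.gi_class == "missing" else r.gi_class == "high"
        active = _combine((lip, ob, gi), combine) or r.validated
        v = AdmetVerdict(
            component_id=r.component_id,
            lipinski_pass=lip,
            ob_pass=ob,
            gi_pass=gi,
            validated=r.validated,
            active=active,
        )
        n_active += active
        n_missing_all += v.all_rules_missing
        out.append(v)
    logger.info(
        "select_active_components: %d/%d active (combine=%s, ob>=%g); "
        "%d record(s) had no usable ADMET data",
        n_active,
        len(out),
        combine,
        ob_threshold,
        n_missing_all,
    )
    return out
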