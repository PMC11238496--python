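"""Construction of SDG indicator 3.7.1 (mDFPS) from raw woman-level fields.

The indicator is defined over women aged 15-49 with a *demand* for family
planning: fecund women who want to space or limit childbearing, plus women
currently using any contraceptive method (revealed demand). Among women
with demand, mDFPS is true exactly when the current method is on the
modern-method list. Pregnant non-users are classified as having no current
demand by default (they cannot currently use a method); a config switch
reclassifies them as in demand when a ``pregnancy_mistimed`` field is
supplied and true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MethodVocabulary",
    "IndicatorResult",
    "is_modern_method",
    "classify_demand",
    "compute_mdfps",
    "apply_indicator",
]

#: Modern methods as printed in the indicator definition this package follows.
MODERN_CORE = frozenset(
    {
        "pills",
        "condom_male",
        "condom_female",
        "injectables",
        "implants",
        "patch",
        "diaphragm",
        "spermicide",
        "emergency_contraception",
    }
)

#: DHS additionally counts these as modern; the printed list omits them. They
#: are included by default and the deviation is logged at vocabulary creation.
MODERN_DHS_EXTRA = frozenset({"iud", "female_sterilization", "male_sterilization"})

TRADITIONAL_DEFAULT = frozenset(
    {"withdrawal", "rhythm", "lactational_amenorrhea_traditional", "other_traditional"}
)

NONE_CODE = "none"


@dataclass(frozen=True)
class MethodVocabulary:
    """Configured contraceptive-method vocabulary.

    ``modern`` and ``traditional`` are disjoint code sets; ``none`` denotes
    non-use. Any other code is an error, never silently non-modern.
    """

    modern: frozenset = field(default_factory=lambda: MODERN_CORE | MODERN_DHS_EXTRA)
    traditional: frozenset = field(default_factory=lambda: TRADITIONAL_DEFAULT)

    def __post_init__(self) -> None:
        overlap = self.modern & self.traditional
        if overlap:
            raise ValueError(f"method codes in both modern and traditional: {sorted(overlap)}")
        if NONE_CODE in self.modern or NONE_CODE in self.traditional:
            raise ValueError("'none' is reserved for non-use")

    @classmethod
    def default(cls) -> "MethodVocabulary":
        vocab = cls()
        logger.info(
            "method vocabulary: counting %s as modern in addition to the core list "
            "(DHS convention; the printed indicator definition omits them)",
            sorted(MODERN_DHS_EXTRA),
        )
        return vocab

    @classmethod
    def from_yaml(cls, path: str) -> "MethodVocabulary":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(modern=frozenset(cfg["modern"]), traditional=frozenset(cfg["traditional"]))

    @property
    def known(self) -> frozenset:
        return self.modern | self.traditional | {NONE_CODE}


@dataclass(frozen=True)
class IndicatorResult:
    woman_id: object
    has_demand: bool
    mdfps: bool | None  # None exactly when has_demand is False

    def __post_init__(self) -> None:
        if self.has_demand and self.mdfps is None:
            raise ValueError("mdfps must be defined for demand-positive women")
        if not self.has_demand and self.mdfps is not None:
            raise ValueError("mdfps is not applicable without demand")


def is_modern_method(method: str, vocab: MethodVocabulary | None = None) -> bool:
    """True exactly for codes on the configured modern list.

    Unknown codes raise (a typo must never be silently treated as
    non-modern use).
    """
    vocab = vocab or MethodVocabulary.default()
    if method not in vocab.known:
        raise ValueError(f"unknown contraceptive method code: {method!r}")
    return method in vocab.modern


def classify_demand(
    record,
    vocab: MethodVocabulary | None = None,
    pregnancy_rule: str = "no_demand",
) -> bool:
    """Does this woman have a demand for family planning?

    True when she is a current user of any method (revealed demand) or is
    fecund and wants to space or limit childbearing. Pregnant non-users
    follow ``pregnancy_rule``: "no_demand" (default) or "mistimed" (in
    demand when record.pregnancy_mistimed is true).
    """
    vocab = vocab or MethodVocabulary.default()
    method = _get(record, "current_method")
    if method is None or (isinstance(method, float) and np.isnan(method)):
        raise ValueError("missing current_method")
    if method not in vocab.known:
        raise ValueError(f"unknown contraceptive method code: {method!r}")
    if method != NONE_CODE:
        return True
    pregnant = _get(record, "pregnant")
    if pregnant:
        if pregnancy_rule == "mistimed":
            return bool(_get(record, "pregnancy_mistimed", False))
        return False
    fecund = _get(record, "fecund")
    pref = _get(record, "fertility_preference")
    if fecund is None or (isinstance(fecund, float) and np.isnan(fecund)):
        raise ValueError("missing fecundity")
    if pref is None or (isinstance(pref, float) and np.isnan(pref)):
        raise ValueError("missing fertility_preference")
    return bool(fecund) and pref in ("wants_to_space", "wants_to_limit")


def compute_mdfps(
    record,
    vocab: MethodVocabulary | None = None,
    pregnancy_rule: str = "no_demand",
) -> IndicatorResult:
    """Demand flag plus, where demand holds, whether it is satisfied by a modern method."""
    vocab = vocab or MethodVocabulary.default()
    demand = classify_demand(record, vocab, pregnancy_rule)
    mdfps = is_modern_method(_get(record, "current_method"), vocab) if demand else None
    return IndicatorResult(woman_id=_get(record, "woman_id"), has_demand=demand, mdfps=mdfps)


def apply_indicator(
    women: pd.DataFrame,
    vocab: MethodVocabulary | None = None,
    pregnancy_rule: str = "no_demand",
) -> tuple[pd.DataFrame, dict]:
    """Vectorised indicator construction for a woman-record table.

    Returns (results, report): results has woman_id, has_demand and a
    nullable-boolean mdfps (pd.NA where no demand); records with missing
    fecundity or fertility preference are excluded and counted in the
    report rather than silently dropped.
    """
    vocab = vocab or MethodVocabulary.default()
    method = women["current_method"].astype(str)
    unknown = ~method.isin(vocab.known)
    if unknown.any():
        raise ValueError(
            f"unknown contraceptive method codes: {sorted(method[unknown].unique())}"
        )

    user = method != NONE_CODE
    pregnant = women["pregnant"].astype(bool)
    missing = women["fecund"].isna() | women["fertility_preference"].isna()
    missing &= ~user  # users are classified regardless of preference fields

    fecund = women["fecund"].fillna(False).astype(bool)
    pref_need = women["fertility_preference"].isin(["wants_to_space", "wants_to_limit"])
    if pregnancy_rule == "mistimed" and "pregnancy_mistimed" in women.columns:
        preg_demand = pregnant & women["pregnancy_mistimed"].fillna(False).astype(bool)
    else:
        preg_demand = pd.Series(False, index=women.index)

    demand = user | np.where(pregnant, preg_demand, fecund & pref_need)
    demand = pd.Series(demand, index=women.index) & ~missing

    mdfps = pd.Series(pd.NA, index=women.index, dtype="boolean")
    mdfps[demand] = method[demand].isin(vocab.modern)

    out = pd.DataFrame(
        {
            "woman_id": women["woman_id"],
            "has_demand": demand.astype(bool),
            "mdfps": mdfps,
        }
    )
    out.loc[missing, "has_demand"] = False
    report = {
        "n_input": int(len(women)),
        "n_excluded_missing": int(missing.sum()),
        "excluded_woman_ids": women.loc[missing, "woman_id"].tolist(),
        "n_demand": int(out["has_demand"].sum()),
        "n_mdfps": int((out["mdfps"] == True).sum()),  # noqa: E712
    }
    return out, report


def _get(record, name: str, default=None):
    if isinstance(record, dict):
        return record.get(name, default)
    return getattr(record, name, default)
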