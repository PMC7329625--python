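"""Phenotype and risk-factor coding.

Constructs the analysis variables from raw measurements: mean spherical
equivalent of the two eyes, the weighted polygenic risk score with its
center-then-binarize coding, questionnaire binarizations (shipped as
per-cohort rule files under ``myopiaqr/rules``), and the parental-myopia
classification.  All binary outputs use the convention 1 = higher myopia
risk.
"""

from __future__ import annotations

import logging
import numbers
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "spherical_equivalent",
    "mean_refractive_error",
    "compute_prs",
    "binarize_prs",
    "CodingRule",
    "load_rules",
    "apply_coding",
    "classify_parent_myopia_alspac",
    "combine_parental_myopia",
]

logger = logging.getLogger(__name__)

# Self-rated distance-vision categories used for ALSPAC parents.
_MYOPIC_RESPONSES = frozenset(
    {"I can't see clearly at a distance", "I can't see much at all"}
)
_NONMYOPIC_RESPONSES = frozenset(
    {"always very good", "I can't see clearly close up"}
)


def spherical_equivalent(sphere, cyl):
    """Spherical equivalent in diopters: sphere + cyl/2.

    Accepts scalars or array-likes; missing inputs propagate to missing
    outputs.
    """
    sphere = np.asarray(sphere, dtype=float)
    cyl = np.asarray(cyl, dtype=float)
    out = sphere + cyl / 2.0
    return float(out) if out.ndim == 0 else out


def mean_refractive_error(se_right, se_left):
    """Average of the two eyes' spherical equivalents.

    If one eye is missing the other eye's value is used; both missing
    yields missing.
    """
    r = np.asarray(se_right, dtype=float)
    l = np.asarray(se_left, dtype=float)
    stacked = np.stack([r, l])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair -> NaN
        out = np.nanmean(stacked, axis=0)
    return float(out) if out.ndim == 0 else out


def compute_prs(panel, impute_missing: bool = True) -> pd.Series:
    """Per-subject polygenic risk score: sum_v weight_v * dosage_vs.

    ``panel`` is a :class:`~myopiaqr.simulate.GenotypePanel` (or anything
    with aligned ``weights`` and ``dosages``).  Missing dosages are
    mean-imputed per variant (2 * allele frequency estimated from the
    observed dosages) unless ``impute_missing=False``, in which case they
    raise.
    """
    dos = panel.dosages
    w = np.asarray(panel.weights, dtype=float)
    if w.shape[0] != dos.shape[0]:
        raise ValueError("weights are not aligned with the dosage matrix")
    mat = dos.to_numpy(dtype=float)
    if np.isnan(mat).any():
        if not impute_missing:
            raise ValueError("missing dosages present and imputation disabled")
        row_means = np.nanmean(mat, axis=1, keepdims=True)
        mat = np.where(np.isnan(mat), row_means, mat)
    scores = w @ mat
    return pd.Series(scores, index=dos.columns, name="prs")


def binarize_prs(scores) -> pd.Series:
    """Center the scores at zero, then code 1 where the centered score is
    below zero (higher genetic myopia risk), 0 otherwise.

    A score exactly at the mean codes 0.  Missing scores propagate.  The
    output is invariant to adding any constant to all scores.
    """
    s = pd.Series(scores, dtype=float)
    if s.notna().sum() < 2:
        raise ValueError("need at least two non-missing scores")
    centered = s - s.mean(skipna=True)
    out = (centered < 0).astype(float)
    out[centered.isna()] = np.nan
    out.name = "genetic_risk"
    return out


@dataclass(frozen=True)
class CodingRule:
    """One questionnaire-to-binary coding rule.

    ``kind="categorical"`` maps declared response strings to {0, 1};
    undeclared responses code as missing with a warning.  ``kind=
    "threshold"`` compares a numeric response to ``value`` with operator
    ``op`` (``"le"``, ``"lt"``, ``"ge"``, ``"gt"``) and emits
    ``coded_when_true`` when the comparison holds.
    """

    name: str
    cohort: str
    kind: str
    mapping: dict | None = None
    op: str | None = None
    value: float | None = None
    coded_when_true: int = 1


def load_rules(cohort: str) -> dict[str, CodingRule]:
    """Load the shipped coding rules for a cohort (``"ALSPAC"`` or
    ``"GenerationR"``)."""
    fname = {"ALSPAC": "alspac.yaml", "GenerationR": "generation_r.yaml"}.get(cohort)
    if fname is None:
        raise KeyError(f"no shipped rules for cohort {cohort!r}")
    text = resources.files("myopiaqr.rules").joinpath(fname).read_text()
    raw = yaml.safe_load(text)
    rules = {}
    for name, spec in raw["rules"].items():
        rules[name] = CodingRule(
            name=name,
            cohort=raw["cohort"],
            kind=spec["type"],
            mapping=spec.get("mapping"),
            op=spec.get("op"),
            value=spec.get("value"),
            coded_when_true=int(spec.get("coded_when_true", 1)),
        )
    return rules


def apply_coding(responses, rule: CodingRule) -> pd.Series:
    """Apply a coding rule to a column of questionnaire responses.

    Returns a float Series in {0.0, 1.0, NaN}.
    """
    s = pd.Series(responses)
    if rule.kind == "categorical":
        out = pd.Series(np.nan, index=s.index, dtype=float)
        known = set(rule.mapping)
        for resp, code in rule.mapping.items():
            out[s == resp] = float(code)
        unseen = s.dropna()[~s.dropna().isin(known)]
        if len(unseen):
            logger.warning(
                "rule %s/%s: %d responses in undeclared categories coded missing: %s",
                rule.cohort, rule.name, len(unseen), sorted(set(unseen))[:5],
            )
        return out
    if rule.kind == "threshold":
        x = pd.to_numeric(s, errors="coerce")
        cmp = {
            "le": x <= rule.value,
            "lt": x < rule.value,
            "ge": x >= rule.value,
            "gt": x > rule.value,
        }[rule.op]
        out = cmp.astype(float).where(x.notna())
        if rule.coded_when_true == 0:
            out = 1.0 - out
        return out
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, numbers.Real) and np.isnan(value):
        return True
    return False


def classify_parent_myopia_alspac(eye1, eye2) -> str | float:
    """Classify one parent from the two per-eye self-rated vision items.

    Both eyes in the "can't see at a distance / can't see much at all"
    set -> ``"myopic"``; both in the "always very good / can't see close
    up" set -> ``"nonmyopic"``; any other combination (including missing
    responses) -> missing (NaN).
    """
    if _is_missing(eye1) or _is_missing(eye2):
        return np.nan
    if eye1 in _MYOPIC_RESPONSES and eye2 in _MYOPIC_RESPONSES:
        return "myopic"
    if eye1 in _NONMYOPIC_RESPONSES and eye2 in _NONMYOPIC_RESPONSES:
        return "nonmyopic"
    return np.nan


def combine_parental_myopia(mother, father) -> float:
    """Child-level parental-myopia factor from two parent classifications.

    1 if at least one parent is myopic; 0 if both are classified
    nonmyopic; missing if no parent is myopic but at least one
    classification is missing (the missing parent could be the myopic
    one).
    """
    m_miss, f_miss = _is_missing(mother), _is_missing(father)
    if (not m_miss and mother == "myopic") or (not f_miss and father == "myopic"):
        return 1.0
    if m_miss or f_miss:
        return np.nan
    if mother == "nonmyopic" and father == "nonmyopic":
        return 0.0
    return np.nan
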