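"""Applicability-domain filtering, five-model consensus voting, and decoy
validation for virtual screening.

A candidate is inside the applicability domain (AD) when its average molecular
weight falls in a 200–700 Da window and its mean Tanimoto similarity to its
five most similar training compounds, under the ECFP4-1024 reference encoding,
is at least 0.4.  Candidates surviving the AD filter are voted on by the five
per-scheme classifiers; three or more active votes make a consensus active.
Decoy validation spikes known actives drawn from the training set into a
screen to confirm the models recover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprints import FingerprintScheme, SCHEMES, encode_matrix
from .modeling import FingerprintClassifierResults
from .structures import Molecule, average_molecular_weight

__all__ = [
    "ADCriteria",
    "ADResult",
    "ScreeningVerdict",
    "ad_filter",
    "consensus_screen",
    "decoy_validation",
    "verdicts_to_frame",
]


@dataclass(frozen=True)
class ADCriteria:
    """Applicability-domain rule: MW window plus nearest-neighbour Tc floor."""

    mw_min: float = 200.0
    mw_max: float = 700.0
    k_neighbors: int = 5
    tc_threshold: float = 0.4
    reference_scheme: FingerprintScheme = FingerprintScheme("ECFP4", 1024)
    use_monoisotopic_mw: bool = False  # sensitivity-analysis alternative

    def __post_init__(self):
        if self.mw_min >= self.mw_max:
            raise ValueError("mw_min must be below mw_max")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.tc_threshold <= 1:
            raise ValueError("tc_threshold must lie in (0, 1]")


@dataclass
class ADResult:
    candidate: Molecule
    ad_pass: bool
    ad_reasons: list[str]
    mean_top_k_tc: float | None
    mw: float | None


@dataclass
class ScreeningVerdict:
    """Per-candidate screening outcome: AD status, votes, consensus."""

    candidate_id: str
    name: str
    ad_pass: bool
    ad_reasons: list[str]
    mw: float | None
    mean_top_k_tc: float | None
    votes: dict[str, str] = field(default_factory=dict)  # scheme -> active/inactive
    n_active_votes: int = 0
    consensus: str = "out_of_domain"  # active | not_active | out_of_domain

    def __post_init__(self):
        assert (self.consensus == "out_of_domain") == (not self.ad_pass)
        if self.ad_pass:
            assert self.consensus == ("active" if self.n_active_votes >= 3 else "not_active")


def _tanimoto_to_train(candidates: Sequence[Molecule], X_train: np.ndarray,
                       scheme: FingerprintScheme) -> np.ndarray:
    """(n_candidates, n_train) Tanimoto matrix; rows for unencodable are NaN."""
    Xc = encode_matrix(candidates, scheme).astype(np.int64)
    Xt = X_train.astype(np.int64)
    inter = Xc @ Xt.T
    union = Xc.sum(1)[:, None] + Xt.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return tc


def ad_filter(
    candidates: Sequence[Molecule],
    train_library: Sequence[Molecule],
    criteria: ADCriteria = ADCriteria(),
) -> list[ADResult]:
    """Apply the applicability-domain rule to each candidate.

    Both failure reasons (``mw_out_of_range``, ``low_neighbor_similarity``)
    are reported when both apply.  A candidate whose structure cannot be
    parsed or encoded is reported out of domain with reason
    ``encoding_failure`` rather than dropped or fatal.
    """
    if not train_library:
        raise ValueError("ad_filter requires a non-empty training library")
    X_train = encode_matrix(train_library, criteria.reference_scheme)
    k = min(criteria.k_neighbors, len(train_library))
    results: list[ADResult] = []
    for cand in candidates:
        if cand.rdkit_mol is None:
            results.append(ADResult(cand, False, ["encoding_failure"], None, None))
            continue
        mw = (
            sum(_mono(cand))
            if criteria.use_monoisotopic_mw
            else average_molecular_weight(cand)
        )
        tc = _tanimoto_to_train([cand], X_train, criteria.reference_scheme)[0]
        top_k = np.sort(tc)[-k:]
        mean_tc = float(top_k.mean())
        reasons = []
        if not criteria.mw_min <= mw <= criteria.mw_max:
            reasons.append("mw_out_of_range")
        if mean_tc < criteria.tc_threshold:
            reasons.append("low_neighbor_similarity")
        results.append(ADResult(cand, not reasons, reasons, mean_tc, mw))
    return results


def _mono(mol: Molecule):
    from .structures import ATOMIC_MASSES

    return (ATOMIC_MASSES[e][0] * c for e, c in mol.element_counts().items())


def _check_models(models: Sequence[FingerprintClassifierResults]) -> None:
    schemes = [m.scheme for m in models]
    if sorted(map(str, schemes)) != sorted(map(str, SCHEMES)):
        raise ValueError(
            "consensus screening requires exactly one model per scheme; got "
            + ", ".join(map(str, schemes))
        )


def consensus_screen(
    candidates: Sequence[Molecule],
    models: Sequence[FingerprintClassifierResults],
    train_library: Sequence[Molecule],
    criteria: ADCriteria = ADCriteria(),
) -> list[ScreeningVerdict]:
    """AD-filter candidates, then let all five models vote on the survivors.

    A consensus ``active`` needs a majority (≥ 3 of 5) of active votes;
    verdicts are sorted by descending vote count, then candidate id, so
    sub-majority compounds remain visible in reports.
    """
    _check_models(models)
    ad_results = ad_filter(candidates, train_library, criteria)
    survivors = [r for r in ad_results if r.ad_pass]
    votes_by_id: dict[str, dict[str, str]] = {r.candidate.id: {} for r in survivors}
    if survivors:
        mols = [r.candidate for r in survivors]
        for model in models:
            active = model.predict_active(mols)
            for r, a in zip(survivors, active):
                votes_by_id[r.candidate.id][str(model.scheme)] = (
                    "active" if a else "inactive"
                )
    verdicts = []
    for r in ad_results:
        if r.ad_pass:
            votes = votes_by_id[r.candidate.id]
            n_active = sum(v == "active" for v in votes.values())
            consensus = "active" if n_active >= 3 else "not_active"
        else:
            votes, n_active, consensus = {}, 0, "out_of_domain"
        verdicts.append(ScreeningVerdict(
            candidate_id=r.candidate.id, name=r.candidate.name,
            ad_pass=r.ad_pass, ad_reasons=r.ad_reasons, mw=r.mw,
            mean_top_k_tc=r.mean_top_k_tc, votes=votes,
            n_active_votes=n_active, consensus=consensus,
        ))
    verdicts.sort(key=lambda v: (-v.n_active_votes, v.candidate_id))
    return verdicts


def decoy_validation(
    models: Sequence[FingerprintClassifierResults],
    train_library: Sequence[Molecule],
    n_decoys: int = 20,
    seed: int = 0,
    require_model_agreement: bool = True,
) -> dict:
    """Spike known actives from the training set into a screen and count
    per-model recovery.

    Eligible decoys are ground-truth-active training compounds predicted
    active by at least one model (``require_model_agreement=False`` relaxes to
    label-only).  The draw is reproducible for a fixed (seed, pool).
    """
    _check_models(models)
    actives = [m for m in train_library if m.label == "active"]
    if require_model_agreement:
        if actives:
            any_active = np.zeros(len(actives), dtype=bool)
            for model in models:
                any_active |= model.predict_active(actives)
            pool = [m for m, flag in zip(actives, any_active) if flag]
        else:
            pool = []
    else:
        pool = actives
    if len(pool) < n_decoys:
        raise ValueError(
            f"eligible decoy pool has {len(pool)} compounds, fewer than the "
            f"requested {n_decoys}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pool), size=n_decoys, replace=False))
    decoys = [pool[i] for i in idx]
    per_model = {
        str(model.scheme): int(model.predict_active(decoys).sum())
        for model in models
    }
    return {
        "n_selected": n_decoys,
        "decoy_ids": [d.id for d in decoys],
        "per_model_recovered": per_model,
        "all_recovered": all(v == n_decoys for v in per_model.values()),
    }


def verdicts_to_frame(verdicts: Sequence[ScreeningVerdict]) -> pd.DataFrame:
    """Screening report table: one row per candidate, one column per scheme."""
    rows = []
    for v in verdicts:
        row = {
            "candidate_id": v.candidate_id,
            "name": v.name,
            "mw": v.mw,
            "mean_top5_tc": v.mean_top_k_tc,
            "ad_pass": v.ad_pass,
            "ad_reasons": ";".join(v.ad_reasons),
        }
        for scheme in SCHEMES:
            row[f"vote_{scheme}"] = v.votes.get(str(scheme), "")
        row["n_active_votes"] = v.n_active_votes
        row["consensus"] = v.consensus
        rows.append(row)
    return pd.DataFrame(rows)
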