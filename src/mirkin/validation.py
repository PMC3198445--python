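"""Quality-of-fit scoring and validation of fitted architectures.

The fit between a model-predicted downstream trajectory D_hat and the
observed trajectory D on the 19-point grid is the *smoothed relative error
of prediction*: the plain relative error |D_hat - D| / D with its
denominator floored at the profile mean, so near-zero observations cannot
inflate it.  Its grid average (x100, percentage valued) is the global
ErrPred.  A network is validated when ErrPred is strictly below the
threshold (default 10%) in every scored condition; a miRNA-mRNA pair is
validated when at least one network containing it is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architectures import TranscrDegrArch, TranslInhibArch
from .errors import AlignmentError, DegenerateProfileError
from .kinetics import TDParams, TIParams
from .profiles import Condition

__all__ = [
    "FitResult",
    "PairVerdict",
    "smoothed_relative_error",
    "errpred_global",
    "validate_network",
    "validate_pairs",
    "rank_networks",
    "summarize_campaign",
    "CampaignSummary",
    "write_fit_results",
]


@dataclass(frozen=True)
class FitResult:
    """A fitted architecture with its per-condition ErrPred (percent)."""

    architecture: TranscrDegrArch | TranslInhibArch
    params: TDParams | TIParams
    errpred: Mapping[Condition, float]
    n_params: int
    validated: bool

    @property
    def worst_errpred(self) -> float:
        return max(self.errpred.values())

    @property
    def arch_id(self) -> str:
        return self.architecture.arch_id


@dataclass(frozen=True)
class PairVerdict:
    """Aggregated verdict for one (miRNA, gene) pair across all its networks."""

    mirna: str
    gene: str
    validated: bool
    mode: str  # "Transcr.Degr." | "Transl.Inhib." | "both" | "none"
    best_networks: tuple[FitResult, ...]
    kinds_tested: frozenset[str] = frozenset()


def smoothed_relative_error(pred: float, obs: float, mean_obs: float) -> float:
    """|pred - obs| / max(obs, mean_obs); finite even where obs is near zero."""
    if mean_obs <= 0:
        raise DegenerateProfileError("profile mean must be positive")
    if pred < 0 or obs < 0:
        raise ValueError("levels must be nonnegative")
    return abs(pred - obs) / max(obs, mean_obs)


def errpred_global(
    pred_profile: Sequence[float],
    obs_profile: Sequence[float],
    aggregation: str = "mean",
) -> float:
    """Global error of prediction, percentage valued.

    Mean (default) or RMS over the 19 grid points of the smoothed relative
    error.  Scale invariant: scaling pred and obs jointly leaves it unchanged.
    """
    pred = np.asarray(pred_profile, dtype=float)
    obs = np.asarray(obs_profile, dtype=float)
    if pred.shape != obs.shape:
        raise AlignmentError(f"profiles of shape {pred.shape} and {obs.shape}")
    mean_obs = float(np.mean(obs))
    if mean_obs <= 0:
        raise DegenerateProfileError("observed profile is identically zero")
    errs = np.abs(pred - obs) / np.maximum(obs, mean_obs)
    if aggregation == "mean":
        return float(np.mean(errs)) * 100.0
    if aggregation == "rms":
        return float(np.sqrt(np.mean(errs**2))) * 100.0
    raise ValueError(f"unknown aggregation {aggregation!r}")


def validate_network(fit: FitResult, threshold: float = 10.0) -> bool:
    """True iff every scored condition's ErrPred is strictly below threshold."""
    if not fit.errpred:
        return False
    return all(e < threshold for e in fit.errpred.values())


def rank_networks(fits: Iterable[FitResult]) -> list[FitResult]:
    """Decreasing reliability: ascending worst-condition ErrPred, ties broken
    by fewer parameters (parsimony), then by architecture id."""
    return sorted(fits, key=lambda f: (f.worst_errpred, f.n_params, f.arch_id))


def validate_pairs(
    fits: Iterable[FitResult], threshold: float | None = None
) -> list[PairVerdict]:
    """Aggregate network fits to per-(miRNA, gene) verdicts.

    A pair is validated iff at least one network containing it is validated;
    ``mode`` records which architecture kinds validated it.  If ``threshold``
    is given, validation is re-derived from the stored ErrPreds; otherwise
    the fits' own validated flags are trusted.
    """
    by_pair: dict[tuple[str, str], list[FitResult]] = {}
    for fit in fits:
        for pair in fit.architecture.pairs:
            by_pair.setdefault(pair, []).append(fit)

    verdicts = []
    for (mirna, gene), pair_fits in sorted(by_pair.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if threshold is None:
            good = [f for f in pair_fits if f.validated]
        else:
            good = [f for f in pair_fits if validate_network(f, threshold)]
        kinds_ok = {f.architecture.kind for f in good}
        if not kinds_ok:
            mode = "none"
        elif len(kinds_ok) == 2:
            mode = "both"
        else:
            mode = next(iter(kinds_ok))
        verdicts.append(
            PairVerdict(
                mirna=mirna,
                gene=gene,
                validated=bool(good),
                mode=mode,
                best_networks=tuple(rank_networks(good)),
                kinds_tested=frozenset(f.architecture.kind for f in pair_fits),
            )
        )
    return verdicts


@dataclass(frozen=True)
class CampaignSummary:
    """Per-gene targeting/validated counts plus the flat validated-pair list."""

    per_gene: pd.DataFrame
    validated_pairs: pd.DataFrame


def summarize_campaign(verdicts: Sequence[PairVerdict]) -> CampaignSummary:
    """Tabulate, per gene and architecture kind, how many miRNAs target it
    and how many were validated, plus the flat list of validated pairs."""
    rows = []
    genes = sorted({v.gene for v in verdicts})
    for gene in genes:
        gene_v = [v for v in verdicts if v.gene == gene]
        for kind in ("Transcr.Degr.", "Transl.Inhib."):
            tested = [v for v in gene_v if kind in v.kinds_tested]
            if not tested:
                continue
            n_valid = sum(1 for v in tested if v.mode in (kind, "both"))
            rows.append(
                {"gene": gene, "kind": kind, "n_targeting": len(tested), "n_validated": n_valid}
            )
    per_gene = pd.DataFrame(rows, columns=["gene", "kind", "n_targeting", "n_validated"])

    pair_rows = [
        {"mirna": v.mirna, "gene": v.gene, "mode": v.mode}
        for v in verdicts
        if v.validated
    ]
    validated_pairs = pd.DataFrame(pair_rows, columns=["mirna", "gene", "mode"])
    return CampaignSummary(per_gene=per_gene, validated_pairs=validated_pairs)


def write_fit_results(fits: Sequence[FitResult], path: str | Path) -> None:
    """Serialize fits as delimited text: id, parameters, ErrPreds, verdict."""
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = []
    for f in fits:
        p = f.params
        if isinstance(p, TDParams):
            rates = f"k_transcr={p.k_transcr:.6g};k_react={p.k_react:.6g};k_deg={p.k_deg:.6g}"
        else:
            rates = f"k_transl={p.k_transl:.6g};k_degP={p.k_degP:.6g}"
        hills = ";".join(f"{mid}:c={hp.c},gamma={hp.gamma:.6g}" for mid, hp in sorted(p.hill.items()))
        rows.append(
            {
                "arch_id": f.arch_id,
                "kind": f.architecture.kind,
                "rates": rates,
                "hill": hills,
                "errpred_WT": f.errpred.get(Condition.WT, float("nan")),
                "errpred_KO": f.errpred.get(Condition.KO, float("nan")),
                "n_params": f.n_params,
                "validated": f.validated,
            }
        )
    cols = ["arch_id", "kind", "rates", "hill", "errpred_WT", "errpred_KO", "n_params", "validated"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
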