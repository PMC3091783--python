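"""The Bayesian adjacent-pair classifier.

A same-strand adjacent gene pair is classified as STU (same transcription
unit) or DTU (different transcription units) from two structural features:
the 10-bp-binned intergenic distance and the Rho-independent terminator
evidence in the intergenic gap.  Three model configurations are supported:

1. distance and terminator presence treated as independent given the class
   (naive Bayes with two marginal tables per class);
2. the joint distribution of distance bin and terminator presence;
3. the joint distribution of distance bin and the terminator confidence
   class (absent / low / mid / high).

The prior P(STU) comes from a geometric model of TU length: if the number
of genes per TU is geometric, P(L = n) = p^(n-1) (1 - p), then the mean TU
length is 1/(1 - p) and the prior probability that a random adjacent pair is
internal to a TU is p = (mean - 1)/mean.  An empirical prior (the STU
fraction of the training pairs) is available for sensitivity analysis.

Class-conditional tables are add-alpha smoothed over the full grid spanned
by the training data, so that feature cells never seen in training (common
when a model trained on one genome is applied to another) still receive a
proper likelihood.  Distance bins outside the trained range are clamped to
the nearest edge bin at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .pairs import SAME_STRAND, AdjacentPair

__all__ = [
    "DisTerModel",
    "estimate_prior_geometric",
    "fit",
    "posterior_stu",
    "classify",
    "classify_pairs",
]

CLASSES = ("STU", "DTU")
_BINARY_STATES = ("absent", "present")
_SCORE_STATES = ("absent", "low", "mid", "high")


def estimate_prior_geometric(mean_tu_length: float) -> float:
    """Prior P(STU pair) under the geometric TU-length model.

    With mean TU length m >= 1, p = (m - 1)/m; the inverse relation
    m = 1/(1 - p) holds.  A genome of all-monocistronic TUs (m = 1) gives
    p = 0.
    """
    if mean_tu_length < 1:
        raise ValueError(f"mean TU length {mean_tu_length} < 1")
    return (mean_tu_length - 1.0) / mean_tu_length


def _term_state(pair: AdjacentPair, config: int) -> str:
    if config == 3:
        return pair.terminator_score_class
    return "present" if pair.terminator_present else "absent"


def _states_for(config: int) -> tuple[str, ...]:
    return _SCORE_STATES if config == 3 else _BINARY_STATES


@dataclass(frozen=True)
class DisTerModel:
    """A fitted pair classifier.

    ``cond`` maps class -> {(bin, term_state): probability} for the joint
    configurations (2, 3); ``bin_marg``/``term_marg`` hold the per-class
    marginals for configuration 1.  All tables sum to one per class.
    """

    config: int
    p_stu_prior: float
    smoothing_alpha: float
    min_bin: int
    max_bin: int
    threshold: float = 0.5
    cond: Mapping[str, Mapping[tuple[int, str], float]] | None = None
    bin_marg: Mapping[str, Mapping[int, float]] | None = None
    term_marg: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.config not in (1, 2, 3):
            raise ValueError(f"unknown model configuration {self.config}")
        if not 0.0 <= self.p_stu_prior <= 1.0:
            raise ValueError("prior outside [0, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold outside [0, 1]")
        tol = 1e-12
        for c in CLASSES:
            if self.config == 1:
                for tbl in (self.bin_marg[c], self.term_marg[c]):
                    if abs(sum(tbl.values()) - 1.0) > 1e-9:
                        raise ValueError(f"conditional table for {c} does not sum to 1")
            else:
                if abs(sum(self.cond[c].values()) - 1.0) > 1e-9:
                    raise ValueError(f"conditional table for {c} does not sum to 1")
        del tol

    @property
    def states(self) -> tuple[str, ...]:
        return _states_for(self.config)

    def clamp_bin(self, b: int) -> int:
        return min(max(b, self.min_bin), self.max_bin)

    def likelihood(self, c: str, b: int, state: str) -> float:
        b = self.clamp_bin(b)
        if self.config == 1:
            return self.bin_marg[c][b] * self.term_marg[c][state]
        return self.cond[c][(b, state)]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload: dict = {
            "format": "dister-model",
            "config": self.config,
            "p_stu_prior": self.p_stu_prior,
            "smoothing_alpha": self.smoothing_alpha,
            "min_bin": self.min_bin,
            "max_bin": self.max_bin,
            "threshold": self.threshold,
        }
        if self.config == 1:
            payload["bin_marg"] = {
                c: {str(b): p for b, p in self.bin_marg[c].items()} for c in CLASSES
            }
            payload["term_marg"] = {c: dict(self.term_marg[c]) for c in CLASSES}
        else:
            payload["cond"] = {
                c: {f"{b}|{s}": p for (b, s), p in self.cond[c].items()}
                for c in CLASSES
            }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DisTerModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        data = json.loads(text)
        kwargs = dict(
            config=data["config"],
            p_stu_prior=data["p_stu_prior"],
            smoothing_alpha=data["smoothing_alpha"],
            min_bin=data["min_bin"],
            max_bin=data["max_bin"],
            threshold=data.get("threshold", 0.5),
        )
        if data["config"] == 1:
            kwargs["bin_marg"] = {
                c: {int(b): p for b, p in data["bin_marg"][c].items()}
                for c in CLASSES
            }
            kwargs["term_marg"] = {c: dict(data["term_marg"][c]) for c in CLASSES}
        else:
            cond = {}
            for c in CLASSES:
                tbl = {}
                for key, p in data["cond"][c].items():
                    b, s = key.split("|")
                    tbl[(int(b), s)] = p
                cond[c] = tbl
            kwargs["cond"] = cond
        return cls(**kwargs)


def fit(
    pairs: Sequence[AdjacentPair],
    config: int = 2,
    smoothing_alpha: float = 1.0,
    prior_mode: str = "geometric",
    mean_tu_length: float | None = None,
    threshold: float = 0.5,
) -> DisTerModel:
    """Fit the classifier on labeled same-strand pairs.

    ``pairs`` must carry labels in {STU, DTU} only (NK pairs and
    leader-peptide pairs are excluded upstream, see
    :func:`dister.pairs.training_pairs`).  Conditional tables are
    add-``smoothing_alpha`` relative frequencies over the full bin x
    terminator-state grid spanned by the training data.  The geometric prior
    mode needs the mean length (in genes) of the curated training TUs;
    the empirical mode uses the training STU fraction.
    """
    if smoothing_alpha < 0:
        raise ValueError("smoothing alpha must be >= 0")
    if config not in (1, 2, 3):
        raise ValueError(f"unknown model configuration {config}")
    labeled = [p for p in pairs if p.label in CLASSES]
    if len(labeled) != len(pairs):
        bad = {p.label for p in pairs} - set(CLASSES)
        raise ValueError(f"training pairs carry labels outside STU/DTU: {sorted(bad)}")
    by_class = {c: [p for p in labeled if p.label == c] for c in CLASSES}
    for c in CLASSES:
        if not by_class[c]:
            raise ValueError(f"cannot fit: no training pairs of class {c}")

    if prior_mode == "geometric":
        if mean_tu_length is None:
            raise ValueError(
                "geometric prior mode needs mean_tu_length (mean gene count "
                "of the curated training TUs)"
            )
        prior = estimate_prior_geometric(mean_tu_length)
    elif prior_mode == "empirical":
        prior = len(by_class["STU"]) / len(labeled)
    else:
        raise ValueError(f"unknown prior mode {prior_mode!r}")

    bins = [p.distance_bin for p in labeled]
    min_bin, max_bin = min(bins), max(bins)
    grid_bins = range(min_bin, max_bin + 1)
    states = _states_for(config)
    a = smoothing_alpha

    if config == 1:
        bin_marg, term_marg = {}, {}
        for c in CLASSES:
            n_c = len(by_class[c])
            bc = {b: a for b in grid_bins}
            tc = {s: a for s in states}
            for p in by_class[c]:
                bc[p.distance_bin] += 1
                tc[_term_state(p, config)] += 1
            zb = n_c + a * len(bc)
            zt = n_c + a * len(tc)
            bin_marg[c] = {b: v / zb for b, v in bc.items()}
            term_marg[c] = {s: v / zt for s, v in tc.items()}
        return DisTerModel(
            config=config,
            p_stu_prior=prior,
            smoothing_alpha=a,
            min_bin=min_bin,
            max_bin=max_bin,
            threshold=threshold,
            bin_marg=bin_marg,
            term_marg=term_marg,
        )

    cond = {}
    for c in CLASSES:
        n_c = len(by_class[c])
        tbl = {(b, s): a for b in grid_bins for s in states}
        for p in by_class[c]:
            tbl[(p.distance_bin, _term_state(p, config))] += 1
        z = n_c + a * len(tbl)
        cond[c] = {cell: v / z for cell, v in tbl.items()}
    return DisTerModel(
        config=config,
        p_stu_prior=prior,
        smoothing_alpha=a,
        min_bin=min_bin,
        max_bin=max_bin,
        threshold=threshold,
        cond=cond,
    )


def posterior_stu(model: DisTerModel, pair: AdjacentPair) -> float:
    """Posterior probability that the pair is co-transcribed.

    Bayes' rule over the two classes: p L_STU / (p L_STU + (1-p) L_DTU),
    with L_c the class-conditional probability of the pair's feature cell.
    Only same-strand pairs have a posterior; opposite-strand pairs are DTU
    by definition.
    """
    if pair.orientation != SAME_STRAND:
        raise ValueError(
            f"{pair.upstream}/{pair.downstream}: posterior is defined for "
            "same-strand pairs only"
        )
    p = model.p_stu_prior
    state = _term_state(pair, model.config)
    l_stu = model.likelihood("STU", pair.distance_bin, state)
    l_dtu = model.likelihood("DTU", pair.distance_bin, state)
    num = p * l_stu
    den = num + (1.0 - p) * l_dtu
    if den == 0.0:  # only possible with alpha = 0 and an unseen cell
        return p
    return num / den


def classify(
    model: DisTerModel, pair: AdjacentPair, threshold: float | None = None
) -> str:
    """Hard call: STU iff the posterior strictly exceeds the threshold."""
    t = model.threshold if threshold is None else threshold
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    return "STU" if posterior_stu(model, pair) > t else "DTU"


def classify_pairs(
    model: DisTerModel,
    pairs: Sequence[AdjacentPair],
    threshold: float | None = None,
) -> dict[tuple[str, str], str]:
    """Calls for a full pair list; opposite-strand pairs are DTU by construction."""
    calls = {}
    for p in pairs:
        key = (p.upstream, p.downstream)
        if p.orientation != SAME_STRAND:
            calls[key] = "DTU"
        else:
            calls[key] = classify(model, p, threshold)
    return calls
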