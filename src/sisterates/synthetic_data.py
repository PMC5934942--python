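"""Synthetic language families with population-dependent gain/loss rates.

The generator realizes the same stochastic model the Poisson engine
assumes, so parameter recovery can be quantified end-to-end: each sister
pair starts from a private ancestral inventory of cognate classes; after
the split each member independently loses each ancestral class with
hazard proportional to ``a_loss * (N/N0)**beta_loss`` per unit branch
length, and gains brand-new, family-unique classes at Poisson rate
``a_gain * (N/N0)**beta_gain`` per unit branch length.  Populations are
drawn log-uniformly (default 1e2..1e7, the span between the smallest and
largest speaker communities in the real sister-pair tables), and
``N0 = sqrt(1e2 * 1e7)`` centres the power law so baseline rates keep
the same meaning whatever beta is.

Detectability of a loss depends on the class being attested outside the
pair: each ancestral class is carried by a randomly chosen outgroup
language with probability ``outgroup_retention``.  A lost class that is
attested nowhere else is *not* recognizable as a loss -- the surviving
member's copy then looks like a gain, exactly as in real data.

Simplifications, by design: gains are always family-unique singletons
(no parallel gains or borrowing), gained classes are not subsequently
lost on the same branch, and ancestral inventories are private to each
pair (outgroups model the rest of the family).  These match the
assumptions under which the counting rules are exact, so that any
mismatch between pipeline counts and simulation truth indicates a defect
in the pipeline, not in the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .poisson_model import fit as poisson_fit
from .rate_counter import count_pair
from .sister_pairs import LanguageMeta, SisterPair
from .wordlist_io import CognateMatrix
from . import contrast_model

__all__ = ["SimConfig", "SimTruth", "simulate_family", "recovery_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one synthetic family.

    Defaults emulate an Austronesian-scale dataset: 80 pairs, a 210-item
    basic-vocabulary list with about one ancestral cognate class per
    concept, pair depths spanning two orders of magnitude, and baseline
    rates that put typical per-language gain/loss counts in the tens.
    """

    n_pairs: int = 80
    n_outgroups: int = 5
    n_concepts: int = 210
    ancestral_classes_per_concept: float = 1.0
    beta_gain: float = 0.0
    beta_loss: float = 0.0
    a_gain: float = 0.05          # gains per unit branch length at N = N0
    a_loss: float = 1.5e-4        # per-class loss hazard per unit branch length at N = N0
    pop_log_range: tuple[float, float] = (2.0, 7.0)   # log10 persons
    bl_range: tuple[float, float] = (50.0, 2000.0)
    outgroup_retention: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_outgroups < 1 or self.n_concepts < 1:
            raise ValueError("n_pairs, n_outgroups and n_concepts must be >= 1")
        if self.a_gain < 0 or self.a_loss < 0 or self.ancestral_classes_per_concept < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.outgroup_retention <= 1.0:
            raise ValueError("outgroup_retention must be in [0, 1]")
        if self.pop_log_range[0] > self.pop_log_range[1]:
            raise ValueError("pop_log_range must be ordered")
        if not 0 < self.bl_range[0] <= self.bl_range[1]:
            raise ValueError("bl_range must be ordered and positive")

    @property
    def pop_center(self) -> float:
        """Geometric centre of the population range; anchors the power law."""
        return 10 ** ((self.pop_log_range[0] + self.pop_log_range[1]) / 2.0)


@dataclass(frozen=True)
class SimTruth:
    """Events actually generated, per language.

    ``gains``/``losses`` are all events written into the matrix;
    ``detectable_losses`` are losses whose class survives in the sister
    (the only losses any sister-pair comparison can in principle see --
    a class lost by both members is indistinguishable from one never
    present).  A detectable loss is *recognized* as a loss only if the
    class is also attested outside the pair; gains, being family-unique,
    are always recognizable.
    """

    gains: dict[str, int]
    losses: dict[str, int]
    detectable_losses: dict[str, int]
    recognizable_losses: dict[str, int]
    config: SimConfig


def simulate_family(
    config: SimConfig,
) -> tuple[CognateMatrix, dict[str, LanguageMeta], str, list[SisterPair], SimTruth]:
    """Generate one synthetic family.

    Returns the cognate matrix, per-language metadata, a Newick tree with
    fully supported cherries, the list of sister pairs (with populations
    attached, oriented as generated), and the generation truth.
    """
    rng = np.random.default_rng(config.seed)
    n0 = config.pop_center

    concepts = [f"c{k:03d}" for k in range(config.n_concepts)]
    pair_langs = [(f"L{j:03d}a", f"L{j:03d}b") for j in range(config.n_pairs)]
    outgroups = [f"OG{k:02d}" for k in range(config.n_outgroups)]
    languages = [lang for pair in pair_langs for lang in pair] + outgroups

    presence: dict[tuple[str, str], set[str]] = {
        (lang, c): set() for lang in languages for c in concepts
    }
    gains = {lang: 0 for lang in languages}
    losses = {lang: 0 for lang in languages}
    detectable = {lang: 0 for lang in languages}
    recognizable = {lang: 0 for lang in languages}
    meta: dict[str, LanguageMeta] = {}
    pairs: list[SisterPair] = []

    log_lo, log_hi = config.pop_log_range
    for j, (la, lb) in enumerate(pair_langs):
        t = rng.uniform(*config.bl_range)
        pops = np.round(10 ** rng.uniform(log_lo, log_hi, size=2)).astype(int)
        pops = np.maximum(pops, 1)
        meta[la] = LanguageMeta(la, int(pops[0]))
        meta[lb] = LanguageMeta(lb, int(pops[1]))
        pairs.append(
            SisterPair(lang1=la, lang2=lb, N1=int(pops[0]), N2=int(pops[1]),
                       support=1.0, branch_length=t)
        )

        # ancestral inventory of this pair, spread over concepts
        n_anc = rng.poisson(config.ancestral_classes_per_concept, size=config.n_concepts)
        loss_rate = config.a_loss * (pops / n0) ** config.beta_loss * t
        p_loss = 1.0 - np.exp(-loss_rate)
        for k, concept in enumerate(concepts):
            for m in range(n_anc[k]):
                cid = f"p{j}_{concept}_anc{m}"
                kept_by = rng.random(2) >= p_loss
                for lang, kept in zip((la, lb), kept_by):
                    if kept:
                        presence[(lang, concept)].add(cid)
                lost_langs = [lang for lang, kept in zip((la, lb), kept_by) if not kept]
                for lang in lost_langs:
                    losses[lang] += 1
                attested_out = rng.random() < config.outgroup_retention
                if attested_out:
                    og = outgroups[int(rng.integers(config.n_outgroups))]
                    presence[(og, concept)].add(cid)
                if len(lost_langs) == 1:
                    detectable[lost_langs[0]] += 1
                    if attested_out:
                        recognizable[lost_langs[0]] += 1

        # gains: brand-new singleton classes
        gain_mean = config.a_gain * (pops / n0) ** config.beta_gain * t
        n_gain = rng.poisson(gain_mean)
        for lang, k_gain in zip((la, lb), n_gain):
            gains[lang] = int(k_gain)
            target_concepts = rng.integers(config.n_concepts, size=k_gain)
            for g, k in enumerate(target_concepts):
                presence[(lang, concepts[k])].add(f"g_{lang}_{g}")

    for og in outgroups:
        meta[og] = LanguageMeta(og, 10_000)

    matrix = CognateMatrix(
        languages,
        concepts,
        presence,
        attested=[(lang, c) for lang in languages for c in concepts],
    )
    tree = _build_newick(pairs, outgroups, max_bl=config.bl_range[1])
    truth = SimTruth(
        gains=gains,
        losses=losses,
        detectable_losses=detectable,
        recognizable_losses=recognizable,
        config=config,
    )
    return matrix, meta, tree, pairs, truth


def _build_newick(
    pairs: list[SisterPair], outgroups: list[str], max_bl: float
) -> str:
    """Caterpillar backbone carrying every cherry, outgroups at the base."""
    depth = 2.0 * max_bl
    clades = [
        f"({p.lang1}:{p.branch_length:g},{p.lang2}:{p.branch_length:g})"
        f"1.0:{depth - p.branch_length:g}"
        for p in pairs
    ]
    clades += [f"{og}:{depth:g}" for og in outgroups]
    tree = clades[0]
    for clade in clades[1:]:
        tree = f"({tree},{clade})1.0:{max_bl:g}"
    return tree + ";"


@dataclass(frozen=True)
class RecoverySummary:
    estimator: str
    response: str
    true_beta: float
    n_replicates: int
    estimates: tuple[float, ...]
    p_values: tuple[float, ...]

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def bias(self) -> float:
        return float(np.mean(self.estimates) - self.true_beta)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean((np.asarray(self.estimates) - self.true_beta) ** 2)))

    def rejection_rate(self, alpha: float = 0.05) -> float:
        return float(np.mean(np.asarray(self.p_values) < alpha))


def recovery_experiment(
    config: SimConfig,
    n_replicates: int,
    estimator: str = "poisson",
    response: str = "loss",
) -> RecoverySummary:
    """Simulate -> count -> fit, repeatedly; summarize recovery of beta.

    Runs the full pipeline (matrix-level counting, not the truth counts)
    per replicate and collects the estimated population exponent and the
    test p-value.  Replicate seeds are derived from ``config.seed``.
    """
    if estimator not in {"poisson", "contrast"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    if response not in {"gain", "loss"}:
        raise ValueError(f"unknown response {response!r}")
    true_beta = config.beta_gain if response == "gain" else config.beta_loss
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    estimates: list[float] = []
    p_values: list[float] = []
    for seed in seeds:
        rep = replace(config, seed=int(seed))
        matrix, _meta, _tree, pairs, _truth = simulate_family(rep)
        counts = [count_pair(matrix, p) for p in pairs]
        if response == "gain":
            c1 = [c.gains1 for c in counts]
            c2 = [c.gains2 for c in counts]
        else:
            c1 = [c.losses1 for c in counts]
            c2 = [c.losses2 for c in counts]
        if estimator == "poisson":
            res = poisson_fit(
                [(p.N1, p.N2) for p in pairs], list(zip(c1, c2))
            )
        else:
            contrasts = contrast_model.compute_contrasts(
                [p.lang1 for p in pairs], c1, c2,
                [p.N1 for p in pairs], [p.N2 for p in pairs],
                [p.branch_length for p in pairs],
            )
            filtered = contrast_model.ww_filter(contrasts)
            res = contrast_model.contrast_regression(list(filtered.retained))
        estimates.append(res.beta_hat)
        p_values.append(res.p_value)
    return RecoverySummary(
        estimator=estimator,
        response=response,
        true_beta=true_beta,
        n_replicates=n_replicates,
        estimates=tuple(estimates),
        p_values=tuple(p_values),
    )
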