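"""Synthetic longitudinal Likert cohorts with a planted two-faction structure.

The generator emulates the statistical shape of an online longitudinal panel
in which two opinion-based factions progressively diverge: a block of
*shared* attitude items on which everyone leans the same way, and a block of
*contested* items on which the minority faction's stance template flips sign
with a per-wave probability that ramps up over time. Behavioural compliance
and epistemic-clarity items are generated with a configurable faction shift
so that downstream group statistics have a known planted effect size.

The generator plants structure; it does not model opinion dynamics
mechanistically. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .survey import ItemSpec, LikertScale, ResponseMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_items",
    "generate_cohort",
    "cohort_summary",
    "write_cohort",
    "DEFAULT_CONTESTED",
    "ATTENTION_EXPECTED",
]

#: prescribed correct response of the attention-check item
ATTENTION_EXPECTED = 3

#: contested trust items: the axis along which the factions split
DEFAULT_CONTESTED = (
    "trust_science",
    "trust_scientists",
    "trust_government",
    "trust_journalists",
)

_SHARED = (
    "trust_doctors",
    "trust_nurses",
    "trust_charity_workers",
    "trust_traditional_healers",
    "trust_community",
    "trust_vaccines",
    "trust_health_advice",
)

_COMPLIANCE = ("compliance_distancing", "compliance_handwashing", "compliance_avoid_crowds")
_CLARITY = ("clarity_understand", "clarity_sense", "clarity_meaningful")


def default_items() -> list[ItemSpec]:
    """11 four-point trust items, 3+3 seven-point behaviour items, 1 attention check."""
    four = LikertScale(1, 4)
    seven = LikertScale(1, 7)
    items = [ItemSpec(i, four, "attitude") for i in _SHARED + DEFAULT_CONTESTED]
    items += [ItemSpec(i, seven, "compliance") for i in _COMPLIANCE]
    items += [ItemSpec(i, seven, "clarity") for i in _CLARITY]
    items.append(ItemSpec("attention_check", seven, "attention"))
    return items


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a three-wave panel of 300 participants splitting 60/40
    into trusting and sceptical factions, with within-faction consensus
    c = 0.85 and a contested-item divergence ramp d = (0.2, 0.5, 0.9).
    """

    n_participants: int = 300
    faction_fractions: tuple[float, float] = (0.6, 0.4)
    n_waves: int = 3
    items: list[ItemSpec] = field(default_factory=default_items)
    contested_items: tuple[str, ...] = DEFAULT_CONTESTED
    consensus_strength: float = 0.85
    divergence_schedule: tuple[float, ...] = (0.2, 0.5, 0.9)
    attrition_rate: float = 0.05
    attention_fail_rate: float = 0.01
    neutral_rate: float = 0.0
    #: faction shift on compliance/clarity latents, Cohen's d on the total latent SD
    behaviour_effect_d: float = 0.3
    #: latent (mean, occasion sd) of the majority faction per behaviour block
    compliance_latent: tuple[float, float] = (5.7, 1.3)
    clarity_latent: tuple[float, float] = (6.4, 0.8)
    #: sd of the persistent per-participant behavioural offset
    subject_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        f0, f1 = self.faction_fractions
        if not (0 < f0 < 1 and 0 < f1 < 1) or abs(f0 + f1 - 1) > 1e-9:
            raise ValueError("faction_fractions must lie in (0,1) and sum to 1")
        if not 0.5 <= self.consensus_strength <= 1:
            raise ValueError("consensus_strength must lie in [0.5, 1]")
        if len(self.divergence_schedule) != self.n_waves:
            raise ValueError("divergence_schedule must have one entry per wave")
        for p in (*self.divergence_schedule, self.attrition_rate,
                  self.attention_fail_rate, self.neutral_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        attitude = {i.item_id for i in self.items if i.block == "attitude"}
        unknown = set(self.contested_items) - attitude
        if unknown:
            raise ValueError(f"contested items {sorted(unknown)} are not attitude items")

    @property
    def faction_sizes(self) -> tuple[int, int]:
        n0 = int(round(self.n_participants * self.faction_fractions[0]))
        return n0, self.n_participants - n0


@dataclass
class GroundTruth:
    """Planted faction labels and per-wave stance templates."""

    faction_of: dict[str, int]
    #: wave_id -> faction -> item_id -> template sign (+1 / -1)
    stance_template: dict[str, dict[int, dict[str, int]]]

    def labels(self, participant_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.faction_of[p] for p in participant_ids])


def _sample_likert(rng: np.random.Generator, sign: np.ndarray,
                   scale: LikertScale) -> np.ndarray:
    """Integer responses uniform over the half of the scale matching each sign."""
    mid = float(scale.midpoint)
    above = np.array([v for v in range(scale.min, scale.max + 1) if v > mid])
    below = np.array([v for v in range(scale.min, scale.max + 1) if v < mid])
    out = np.empty(sign.shape, dtype=float)
    pos, neg, neu = sign > 0, sign < 0, sign == 0
    out[pos] = rng.choice(above, size=int(pos.sum()))
    out[neg] = rng.choice(below, size=int(neg.sum()))
    out[neu] = mid
    return out


def generate_cohort(config: SyntheticConfig) -> tuple[list[ResponseMatrix], GroundTruth]:
    """Draw a reproducible multi-wave cohort with planted factions.

    Stance model per attitude item: the response sign equals the faction's
    template with probability c (= ``consensus_strength``), is opposite with
    probability (1-c)(1-``neutral_rate``), and sits at the scale midpoint
    otherwise (only on scales where the midpoint is attainable). Contested
    items flip the minority faction's template to -1 at wave t when the
    item's fixed uniform draw falls below d_t, so a non-decreasing schedule
    yields a nested, growing set of flipped items.
    """
    n0, n1 = config.faction_sizes
    if n0 < 1 or n1 < 1:
        raise ValueError(f"infeasible config: faction sizes {n0}/{n1}")
    rng = np.random.default_rng(config.seed)
    c = config.consensus_strength

    pids = np.array([f"P{i:04d}" for i in range(config.n_participants)])
    faction = np.array([0] * n0 + [1] * n1)
    attitude = [i for i in config.items if i.block == "attitude"]
    contested = set(config.contested_items)
    # one uniform per contested item, fixed across waves: flipped iff u <= d_t
    flip_u = {i: rng.uniform() for i in config.contested_items}

    # persistent behavioural latent offsets (individual differences)
    subj_offset = rng.normal(0.0, config.subject_sd, size=config.n_participants)

    waves: list[ResponseMatrix] = []
    template: dict[str, dict[int, dict[str, int]]] = {}
    present = np.ones(config.n_participants, dtype=bool)

    for t in range(config.n_waves):
        wave_id = f"T{t + 1}"
        d_t = config.divergence_schedule[t]
        if t > 0 and config.attrition_rate > 0:
            present &= rng.uniform(size=config.n_participants) >= config.attrition_rate
        tmpl_wave = {0: {}, 1: {}}
        for spec in attitude:
            tmpl_wave[0][spec.item_id] = 1
            tmpl_wave[1][spec.item_id] = (
                -1 if spec.item_id in contested and flip_u[spec.item_id] <= d_t else 1
            )
        template[wave_id] = tmpl_wave

        idx = np.flatnonzero(present)
        m = len(idx)
        cols: dict[str, np.ndarray] = {}
        for spec in attitude:
            tmpl = np.array([tmpl_wave[f][spec.item_id] for f in faction[idx]])
            u = rng.uniform(size=m)
            sign = np.where(u < c, tmpl, -tmpl)
            if config.neutral_rate > 0 and spec.scale.has_attainable_midpoint:
                sign = np.where(u >= c + (1 - c) * (1 - config.neutral_rate), 0, sign)
            cols[spec.item_id] = _sample_likert(rng, sign, spec.scale)

        for block, (mu, sd) in (("compliance", config.compliance_latent),
                                ("clarity", config.clarity_latent)):
            block_items = [i for i in config.items if i.block == block]
            if not block_items:
                continue
            # behaviour_effect_d targets the k-item scale *score*, whose sd is
            # sqrt(subject_sd^2 + sd^2 / k) (occasion noise averages out)
            score_sd = float(np.sqrt(config.subject_sd ** 2 + sd ** 2 / len(block_items)))
            shift = config.behaviour_effect_d * score_sd
            for spec in block_items:
                latent = (mu - shift * faction[idx] + subj_offset[idx]
                          + rng.normal(0.0, sd, size=m))
                cols[spec.item_id] = np.clip(np.rint(latent), spec.scale.min, spec.scale.max)

        for spec in (i for i in config.items if i.block == "attention"):
            fail = rng.uniform(size=m) < config.attention_fail_rate
            wrong_pool = [v for v in range(spec.scale.min, spec.scale.max + 1)
                          if v != ATTENTION_EXPECTED]
            resp = np.full(m, float(ATTENTION_EXPECTED))
            if fail.any():
                resp[fail] = rng.choice(wrong_pool, size=int(fail.sum()))
            cols[spec.item_id] = resp

        data = pd.DataFrame(cols, index=pids[idx])[[i.item_id for i in config.items]]
        waves.append(ResponseMatrix(wave_id, list(config.items), data))

    truth = GroundTruth(
        faction_of={p: int(f) for p, f in zip(pids, faction)},
        stance_template=template,
    )
    return waves, truth


def cohort_summary(waves: Sequence[ResponseMatrix], truth: GroundTruth,
                   contested_items: Sequence[str] = DEFAULT_CONTESTED) -> pd.DataFrame:
    """Per-wave, per-attitude-item audit of the planted structure.

    Columns: faction sizes, within-faction consensus (fraction of stances
    matching the faction's template) and the between-faction mean stance gap.
    """
    from .network import binarize  # local import: avoid a hard module cycle

    rows = []
    for wave in waves:
        unknown = [p for p in wave.participant_ids if p not in truth.faction_of]
        if unknown:
            raise ValueError(f"participants not in ground truth: {unknown[:5]}")
        stance = binarize(wave)
        labels = truth.labels(wave.participant_ids)
        tmpl = truth.stance_template[wave.wave_id]
        n_f = {f: int((labels == f).sum()) for f in (0, 1)}
        for spec in wave.items:
            if spec.block != "attitude":
                continue
            s = stance.stances[spec.item_id].to_numpy(dtype=float)
            cons, mean_stance = {}, {}
            for f in (0, 1):
                sf = s[labels == f]
                sf = sf[~np.isnan(sf)]
                cons[f] = float(np.mean(sf == tmpl[f][spec.item_id])) if sf.size else np.nan
                mean_stance[f] = float(np.mean(sf)) if sf.size else np.nan
            rows.append({
                "wave_id": wave.wave_id,
                "item_id": spec.item_id,
                "contested": spec.item_id in set(contested_items),
                "n_faction0": n_f[0],
                "n_faction1": n_f[1],
                "consensus_f0": cons[0],
                "consensus_f1": cons[1],
                "stance_gap": mean_stance[0] - mean_stance[1],
            })
    return pd.DataFrame(rows)


def write_cohort(waves: Sequence[ResponseMatrix], truth: GroundTruth,
                 out_dir: str | Path) -> None:
    """Write one CSV per wave plus a ground-truth faction/template CSV."""
    from .survey import write_wave

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for wave in waves:
        write_wave(wave, out / f"{wave.wave_id}.csv")
    pd.DataFrame(
        {"participant_id": list(truth.faction_of), "faction": list(truth.faction_of.values())}
    ).to_csv(out / "ground_truth.csv", index=False)
    tmpl_rows = [
        {"wave_id": w, "faction": f, "item_id": i, "template_sign": s}
        for w, per_f in truth.stance_template.items()
        for f, items in per_f.items()
        for i, s in items.items()
    ]
    pd.DataFrame(tmpl_rows).to_csv(out / "stance_templates.csv", index=False)
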