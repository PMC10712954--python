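"""CNN-informed stimulus-pair selection.

The search looks for target/distractor pairs whose classification-score
profile dissociates early and late stages of the feature hierarchy: pairs
where the mean score of sublayers 1-3 is close to zero while sublayers 11-13
score high (*zero vs high*), and pairs with the opposite profile
(*high vs zero*).  Candidate pairs are sampled at random from a large pool of
transformed sub-grid stimuli, their early/late mean scores are expressed in
units of the across-candidate standard deviation, and thresholds on those
z-values pick the dissociating pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .backbone import EARLY_LAYERS, LATE_LAYERS
from .decoder import DecoderEnsemble, pair_id, spec_id
from .stimuli import (
    DEFAULT_SUBGRID,
    LIGHT_LOCATIONS,
    ProtocolDef,
    RenderConfig,
    ROTATION_ANGLES,
    StimulusSpec,
    Subgrid,
    render,
)

__all__ = [
    "CandidatePair",
    "SelectionCriteria",
    "SelectionResult",
    "default_pool",
    "sample_candidates",
    "standardize",
    "filter_select",
    "build_informed_protocol",
]


@dataclass
class CandidatePair:
    """One sampled target/distractor pair with early/late score summaries."""

    target: StimulusSpec
    distractor: StimulusSpec
    early_mean: float
    late_mean: float
    early_z: float = float("nan")
    late_z: float = float("nan")

    @property
    def pair_id(self) -> str:
        return pair_id(self.target, self.distractor)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds (in SD units) defining a dissociation profile.

    ``zero_vs_high`` keeps pairs with |early_z| <= tau_zero and
    late_z >= tau_high; ``high_vs_zero`` the mirror image.
    """

    profile: str
    tau_zero: float = 0.5
    tau_high: float = 1.5
    k: int = 7

    def __post_init__(self) -> None:
        if self.profile not in ("zero_vs_high", "high_vs_zero"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if not self.tau_zero < self.tau_high:
            raise ValueError("tau_zero must be < tau_high")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of filtering: picks, survivor count, and population SDs."""

    criteria: SelectionCriteria
    selected: list
    n_survivors: int
    early_sd: float
    late_sd: float
    underfull: bool

    def report(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "pair_id": c.pair_id,
            "target_id": spec_id(c.target),
            "distractor_id": spec_id(c.distractor),
            "early_mean": c.early_mean, "late_mean": c.late_mean,
            "early_z": c.early_z, "late_z": c.late_z,
            "profile": self.criteria.profile,
        } for c in self.selected])


def default_pool(subgrid: Subgrid = DEFAULT_SUBGRID,
                 target_cells: Sequence[tuple[int, int]] = ((0, 0), (0, 1), (1, 0)),
                 distractor_cells: Sequence[tuple[int, int]] = ((3, 3), (3, 2), (2, 3)),
                 rotations: Sequence[int] = ROTATION_ANGLES,
                 lights: Sequence[str] = LIGHT_LOCATIONS,
                 ) -> tuple[list[StimulusSpec], list[StimulusSpec]]:
    """The stimulus pool the informed pairs are drawn from.

    Three shapes per class (defaulting to the sub-grid cells nearest the
    trained corners) crossed with every rotation triple and light location:
    3 x 7^3 x 5 = 5,145 candidate stimuli per class.
    """
    def expand(cells, role):
        out = []
        for row, col in cells:
            base = replace(subgrid.spec_at(row, col), role=role)
            for rx in rotations:
                for ry in rotations:
                    for rz in rotations:
                        for light in lights:
                            out.append(base.with_transform(
                                rot_x=rx, rot_y=ry, rot_z=rz, light_location=light))
        return out

    return expand(target_cells, "target"), expand(distractor_cells, "distractor")


def sample_candidates(ensemble: DecoderEnsemble,
                      targets: Sequence[StimulusSpec],
                      distractors: Sequence[StimulusSpec],
                      n_iter: int = 10_000,
                      seed: int = 0,
                      cfg: RenderConfig | None = None) -> list[CandidatePair]:
    """Sample ``n_iter`` pairs uniformly with replacement and score them.

    Duplicate draws are collapsed to one candidate each.  Rendered images and
    hyperplane distances are cached per stimulus, so cost scales with the
    number of distinct stimuli drawn, not with ``n_iter``.
    """
    if not targets or not distractors:
        raise ValueError("candidate pool must be non-empty")
    rng = np.random.default_rng(seed)
    t_draw = rng.integers(0, len(targets), size=n_iter)
    d_draw = rng.integers(0, len(distractors), size=n_iter)

    pairs = list(dict.fromkeys(
        (int(ti), int(di)) for ti, di in zip(t_draw, d_draw)))

    needed = list(dict.fromkeys(
        [targets[ti] for ti, _ in pairs] + [distractors[di] for _, di in pairs]))
    dist_of = {}
    batch = 64
    for i in range(0, len(needed), batch):
        chunk = needed[i:i + batch]
        imgs = np.stack([render(s, cfg).pixels for s in chunk])
        d = ensemble.distances(imgs)
        dist_of.update({s: d[j] for j, s in enumerate(chunk)})

    early = [i - 1 for i in EARLY_LAYERS]
    late = [i - 1 for i in LATE_LAYERS]
    out = []
    for ti, di in pairs:
        t, d = targets[ti], distractors[di]
        scores = dist_of[t] - dist_of[d]
        out.append(CandidatePair(
            target=t, distractor=d,
            early_mean=float(scores[early].mean()),
            late_mean=float(scores[late].mean()),
        ))
    return out


def standardize(candidates: Sequence[CandidatePair]) -> tuple[list[CandidatePair], float, float]:
    """Express early/late means in units of their across-candidate SD.

    Returns the updated candidates plus the two population SDs.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to standardize")
    early = np.array([c.early_mean for c in candidates])
    late = np.array([c.late_mean for c in candidates])
    early_sd = float(early.std(ddof=0))
    late_sd = float(late.std(ddof=0))
    if early_sd == 0.0 or late_sd == 0.0:
        raise ValueError("degenerate candidate population: zero spread")
    for c in candidates:
        c.early_z = c.early_mean / early_sd
        c.late_z = c.late_mean / late_sd
    return list(candidates), early_sd, late_sd


def filter_select(candidates: Sequence[CandidatePair],
                  criteria: SelectionCriteria) -> SelectionResult:
    """Apply the profile thresholds and keep the top-k dissociating pairs.

    Survivors are ranked by the "high"-side z descending (ties by pair id);
    the picks additionally use distinct targets and distinct distractors so a
    k x k protocol cross can be formed.  If fewer than k survivors exist, all
    are returned with ``underfull`` flagged.
    """
    cands = [c for c in candidates if np.isfinite(c.early_z) and np.isfinite(c.late_z)]
    if len(cands) != len(candidates):
        raise ValueError("candidates must be standardized first")
    early = np.array([c.early_mean for c in cands])
    late = np.array([c.late_mean for c in cands])
    early_sd = float(early.std(ddof=0))
    late_sd = float(late.std(ddof=0))

    if criteria.profile == "zero_vs_high":
        survivors = [c for c in cands
                     if abs(c.early_z) <= criteria.tau_zero and c.late_z >= criteria.tau_high]
        rank_key = lambda c: (-c.late_z, c.pair_id)
    else:
        survivors = [c for c in cands
                     if abs(c.late_z) <= criteria.tau_zero and c.early_z >= criteria.tau_high]
        rank_key = lambda c: (-c.early_z, c.pair_id)

    # dedupe by spec pair
    survivors = list({c.pair_id: c for c in survivors}.values())
    survivors.sort(key=rank_key)

    selected, used_t, used_d = [], set(), set()
    for c in survivors:
        if c.target in used_t or c.distractor in used_d:
            continue
        selected.append(c)
        used_t.add(c.target)
        used_d.add(c.distractor)
        if len(selected) == criteria.k:
            break

    return SelectionResult(
        criteria=criteria, selected=selected, n_survivors=len(survivors),
        early_sd=early_sd, late_sd=late_sd,
        underfull=len(selected) < criteria.k,
    )


def build_informed_protocol(result: SelectionResult,
                            subgrid: Subgrid = DEFAULT_SUBGRID) -> ProtocolDef:
    """Assemble the k x k protocol from the selected pairs.

    The protocol crosses the k selected targets with the k selected
    distractors (7 + 7 stimuli -> 49 pairs at the default k), matching the
    published design.
    """
    ts = [c.target for c in result.selected]
    ds = [c.distractor for c in result.selected]
    pairs = tuple((t, d) for t in ts for d in ds)
    return ProtocolDef(
        name=result.criteria.profile,
        pairs=pairs,
        old_pair=(subgrid.base_target, subgrid.base_distractor),
    )
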