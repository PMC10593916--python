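"""Selection of "Max"/"Avg" natural stimuli and session assembly.

"Max" sets are the candidate images with the highest predicted activation
under an encoding model; "Avg" sets are the images whose predicted
activation is closest to zero in absolute value, i.e. closest to the
average response on the (z-scored) response scale.  Session 1 shows group
Max/Avg sets of natural and synthetic images for several target regions;
Session 2 shows personalized ("Self"), other-subject ("Other") and group
Max sets for one region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fwrf import predict_batch
from .synthetic_data import (ImageStim, MANIFEST_COLUMNS, SessionDesign,
                             SetEntry, StimulusPool)

SESSION1_CONDITIONS = ("GroupMaxNat", "GroupAvgNat", "GroupMaxSyn", "GroupAvgSyn")
SESSION2_CONDITIONS = ("SelfMaxSyn", "SelfMaxNat", "OtherMaxSyn", "OtherMaxNat",
                       "GroupMaxSyn", "GroupMaxNat")


@dataclass
class StimulusSet:
    """An ordered condition set; Max sets descend by predicted activation,
    Avg sets ascend by its absolute value."""

    condition: str
    provider: str
    stimuli: list[ImageStim]
    predictions: np.ndarray | None = field(default=None, repr=False)

    @property
    def image_ids(self) -> list[str]:
        return [s.image_id for s in self.stimuli]

    def __len__(self) -> int:
        return len(self.stimuli)


def _candidates(pool) -> list[ImageStim]:
    if isinstance(pool, StimulusPool):
        return list(pool.stimuli)
    return list(pool)


def _ranked_set(pool, model, N: int, key, condition: str, provider: str,
                predictions: np.ndarray | None = None) -> StimulusSet:
    cands = _candidates(pool)
    if N > len(cands):
        raise ValueError(f"requested {N} images from a pool of {len(cands)}")
    if predictions is not None:
        preds = np.asarray(predictions, dtype=float)
        if len(preds) != len(cands):
            raise ValueError("predictions and pool differ in length")
    else:
        px = np.asarray([s.pixels for s in cands])
        preds = predict_batch(model, px)
    order = sorted(range(len(cands)),
                   key=lambda i: (key(preds[i]), cands[i].image_id))
    top = order[:N]
    return StimulusSet(condition=condition, provider=provider,
                       stimuli=[cands[i] for i in top],
                       predictions=preds[top])


def select_max(pool, model, N: int, *, condition: str = "Max",
               provider: str = "",
               predictions: np.ndarray | None = None) -> StimulusSet:
    """Top-N images by predicted activation, descending; ties by image id."""
    return _ranked_set(pool, model, N, lambda p: -p, condition, provider,
                       predictions)


def select_avg(pool, model, N: int, *, condition: str = "Avg",
               provider: str = "",
               predictions: np.ndarray | None = None) -> StimulusSet:
    """N images with predicted activation closest to zero in absolute value."""
    return _ranked_set(pool, model, N, abs, condition, provider, predictions)


# ---------------------------------------------------------------------------
# Session 1
# ---------------------------------------------------------------------------

def assemble_session1(pool: StimulusPool, group_models: Mapping[str, object],
                      synth_sets: Mapping[tuple[str, str], StimulusSet],
                      N: int = 40, *, n_repeats: int = 2,
                      exclude_shared: bool = True,
                      disjoint_max_avg: bool = True,
                      ) -> tuple[SessionDesign, dict[tuple[str, str], StimulusSet]]:
    """Build the four condition sets per target region for Session 1.

    Natural candidates are the subject-unique pool images (shared images
    are excluded); ``synth_sets`` supplies the pre-generated synthetic
    Max/Avg sets keyed by (region, "Max"|"Avg").  By construction each
    region's Avg natural set is selected from the pool minus its Max set so
    the two cannot overlap (configurable), and the regions' natural sets
    are kept disjoint from one another (a desk-scale pool makes cross-
    region collisions likely, and a session needs unique image ids).
    """
    natural = pool.unique if exclude_shared else list(pool.stimuli)
    entries: list[SetEntry] = []
    sets: dict[tuple[str, str], StimulusSet] = {}
    used: set[str] = set()
    for region, model in group_models.items():
        provider = f"group-{region}"
        avail = [s for s in natural if s.image_id not in used]
        max_nat = select_max(avail, model, N, condition="GroupMaxNat",
                             provider=provider)
        remaining = [s for s in avail
                     if s.image_id not in set(max_nat.image_ids)] \
            if disjoint_max_avg else avail
        if len(remaining) < N:
            warnings.warn("pool too small for disjoint Max/Avg natural sets; "
                          "allowing overlap")
            remaining = avail
        avg_nat = select_avg(remaining, model, N, condition="GroupAvgNat",
                             provider=provider)
        used |= set(max_nat.image_ids) | set(avg_nat.image_ids)
        for st in (max_nat, avg_nat):
            st.stimuli = [s.relabeled(condition=st.condition,
                                      target_region=region)
                          for s in st.stimuli]
        sets[(region, "GroupMaxNat")] = max_nat
        sets[(region, "GroupAvgNat")] = avg_nat
        sets[(region, "GroupMaxSyn")] = synth_sets[(region, "Max")]
        sets[(region, "GroupAvgSyn")] = synth_sets[(region, "Avg")]
        for cond in SESSION1_CONDITIONS:
            src = "natural" if cond.endswith("Nat") else "synthetic"
            entries.append(SetEntry(condition=f"{region}:{cond}", source=src,
                                    provider=provider, count=N))
    design = SessionDesign(session=1, entries=entries,
                           target_regions=list(group_models), n_repeats=n_repeats)
    return design, sets


def session1_sets_by_condition(sets: Mapping[tuple[str, str], StimulusSet]
                               ) -> dict[str, list[ImageStim]]:
    """Key Session-1 sets by the manifest condition label ``region:cond``."""
    return {f"{region}:{cond}": list(st.stimuli)
            for (region, cond), st in sets.items()}


# ---------------------------------------------------------------------------
# Session 2
# ---------------------------------------------------------------------------

def assemble_session2(self_sets: Mapping[str, Mapping[str, StimulusSet]],
                      group_sets: Mapping[str, StimulusSet],
                      counts: tuple[int, int, int] = (32, 20, 12),
                      seed: int = 0, *, region: str = "FFA1",
                      n_repeats: int = 2,
                      ) -> dict[str, tuple[SessionDesign, dict[str, list[ImageStim]]]]:
    """Per-subject Session-2 designs from Self / Other / Group Max sets.

    ``self_sets[subject][source]`` (source "Nat" or "Syn") are each
    subject's personalized Max sets; ``group_sets[source]`` the Session-1
    group Max sets for the target region.  For each subject and source the
    session takes ``n_self`` of their own images, ``n_other`` sampled
    without replacement from the union of the other subjects' sets
    (stratified equally across subjects where divisible, remainder by
    seeded draw) and ``n_group`` group images.  Duplicate image ids within
    one subject's session are avoided by skipping already-used images when
    drawing the Other and Group portions.
    """
    n_self, n_other, n_group = counts
    subjects = list(self_sets)
    out: dict[str, tuple[SessionDesign, dict[str, list[ImageStim]]]] = {}
    root = np.random.SeedSequence([seed, 23])
    subject_seeds = root.spawn(len(subjects))
    for subj, sseq in zip(subjects, subject_seeds):
        rng = np.random.default_rng(sseq)
        sets: dict[str, list[ImageStim]] = {}
        entries: list[SetEntry] = []
        used: set[str] = set()
        for source in ("Syn", "Nat"):
            src_name = "synthetic" if source == "Syn" else "natural"
            own = self_sets[subj][source]
            if len(own) < n_self:
                raise ValueError(f"subject {subj}: fewer than {n_self} "
                                 f"Self{source} images available")
            cond = f"SelfMax{source}"
            chosen = [s.relabeled(condition=cond, target_region=region)
                      for s in own.stimuli[:n_self]]
            used.update(s.image_id for s in chosen)
            sets[cond] = chosen
            entries.append(SetEntry(cond, src_name, f"self-{subj}", n_self))

            # Other: stratified across the other subjects
            others = [t for t in subjects if t != subj]
            base, rem = divmod(n_other, len(others)) if others else (0, 0)
            quota = {t: base for t in others}
            for t in rng.choice(others, size=rem, replace=False):
                quota[t] += 1
            other_imgs: list[ImageStim] = []
            cond = f"OtherMax{source}"
            for t in others:
                avail = [s for s in self_sets[t][source].stimuli
                         if s.image_id not in used]
                if len(avail) < quota[t]:
                    raise ValueError(
                        f"subject {subj}: not enough unused Other{source} "
                        f"images from {t}")
                pick = rng.choice(len(avail), size=quota[t], replace=False)
                for i in sorted(pick):
                    im = avail[i].relabeled(condition=cond, target_region=region)
                    other_imgs.append(im)
                    used.add(im.image_id)
            sets[cond] = other_imgs
            entries.append(SetEntry(cond, src_name, "other", n_other))

            # Group: first n_group session-1 group images not already used
            cond = f"GroupMax{source}"
            avail = [s for s in group_sets[source].stimuli
                     if s.image_id not in used]
            if len(avail) < n_group:
                raise ValueError(f"subject {subj}: not enough unused "
                                 f"Group{source} images")
            grp = [s.relabeled(condition=cond, target_region=region)
                   for s in avail[:n_group]]
            used.update(s.image_id for s in grp)
            sets[cond] = grp
            entries.append(SetEntry(cond, src_name, "group", n_group))
        design = SessionDesign(session=2, entries=entries,
                               target_regions=[region], n_repeats=n_repeats)
        out[subj] = (design, sets)
    return out


def session_manifest(sets: Mapping[str, Sequence[ImageStim]],
                     design: SessionDesign) -> pd.DataFrame:
    rows = []
    for entry in design.entries:
        for im in list(sets[entry.condition])[:entry.count]:
            rows.append({"image_id": im.image_id, "file": f"{im.image_id}.png",
                         "source": im.source, "condition": entry.condition,
                         "target_region": im.target_region or "",
                         "class_label": im.class_label})
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
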