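"""Synthetic data generation for a longitudinal anchor-items linking design.

Emulates a four-wave reading-competence assessment in the style of a national
educational panel: four 25-item Rasch-scaled test forms administered at time
points t1-t4, with decelerating latent growth (means 0.0, 0.7, 1.2, 1.5 logits,
unit variances) and blocks of common (anchor) items shared by adjacent forms.
Anchor difficulties are drawn around the midpoint of the two ability
distributions they must serve, giving good test targeting at both waves.

Model misfit is emulated by generating responses from a 2PL model whose
discriminations are drawn from N(1, 0.14^2); the fitted model is always the
Rasch model, so these draws constitute moderate model-data misfit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit


class ConfigurationError(ValueError):
    """Raised when a study design or calibration request is infeasible."""


#: number of candidate anchor slots shared by each adjacent form pair
N_ANCHOR_SLOTS = 9

#: anchor slot positions (1-based, within the 9-slot block of a form pair)
#: keyed by (anchor_count, pair) where pair t denotes forms (t, t+1)
ANCHOR_POSITIONS: Mapping[tuple[int, int], tuple[int, ...]] = {
    (3, 1): (2, 5, 8),
    (3, 2): (2, 5, 8),
    (3, 3): (2, 5, 8),
    (5, 1): (2, 3, 4, 6, 9),
    (5, 2): (1, 5, 6, 7, 8),
    (5, 3): (2, 3, 4, 6, 9),
    (7, 1): (1, 2, 4, 5, 6, 7, 9),
    (7, 2): (1, 3, 4, 5, 6, 8, 9),
    (7, 3): (1, 3, 4, 5, 6, 7, 9),
    (9, 1): tuple(range(1, 10)),
    (9, 2): tuple(range(1, 10)),
    (9, 3): tuple(range(1, 10)),
}

ALLOWED_ANCHOR_COUNTS = (3, 5, 7, 9)


def substream_rng(master_seed: int, *keys) -> np.random.Generator:
    """Independent, order-insensitive random substream for (master_seed, keys).

    Keys may be ints, bools or strings; strings are folded to integers with a
    stable CRC so the stream does not depend on Python's randomized hashing.
    """
    import zlib

    entropy = [int(master_seed) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        elif isinstance(k, (bool, np.bool_)):
            entropy.append(int(k))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------

def rasch_probability(beta, delta):
    """P(X=1 | beta, delta) = logistic(beta - delta) under the Rasch model.

    Accepts scalars or broadcastable arrays of logits; numerically stable for
    |beta - delta| well beyond +/-40.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(delta))):
        raise ValueError("rasch_probability requires finite inputs")
    return expit(beta - delta)


def twopl_probability(beta, delta, alpha):
    """2PL response probability logistic(alpha * (beta - delta)).

    Used only to *generate* misfitting data; reduces to the Rasch model when
    alpha == 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(~np.isfinite(alpha)) or np.any(alpha <= 0):
        raise ValueError("discrimination alpha must be finite and > 0")
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(delta))):
        raise ValueError("twopl_probability requires finite inputs")
    return expit(alpha * (beta - delta))


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one data-generating condition.

    The defaults are the study conditions: four 25-item forms, latent means
    0.0 / 0.7 / 1.2 / 1.5 logits with unit variance, and (under misfit)
    discriminations drawn from N(1, alpha_sd^2).
    """

    n_timepoints: int = 4
    form_length: int = 25
    true_means: tuple[float, ...] = (0.0, 0.7, 1.2, 1.5)
    true_variances: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    sample_size: int = 500
    misfit: bool = False
    alpha_sd: float = 0.14
    alpha_floor: float = 0.05  # truncation guard for the ~1e-12 negative draw

    def __post_init__(self):
        if len(self.true_means) != self.n_timepoints:
            raise ConfigurationError("true_means needs one entry per time point")
        if len(self.true_variances) != self.n_timepoints:
            raise ConfigurationError("true_variances needs one entry per time point")
        if self.alpha_sd <= 0:
            raise ConfigurationError("alpha_sd must be positive")
        if self.sample_size < 0:
            raise ConfigurationError("sample_size must be non-negative")
        # interior forms carry two 9-slot anchor blocks
        if self.form_length < 2 * N_ANCHOR_SLOTS:
            raise ConfigurationError(
                f"form_length {self.form_length} cannot host two "
                f"{N_ANCHOR_SLOTS}-slot anchor blocks"
            )

    def n_unique_items(self, timepoint: int) -> int:
        n_blocks = sum(
            (1 if timepoint > 1 else 0, 1 if timepoint < self.n_timepoints else 0)
        )
        return self.form_length - n_blocks * N_ANCHOR_SLOTS


# ---------------------------------------------------------------------------
# item bank
# ---------------------------------------------------------------------------

@dataclass
class ItemBank:
    """Item parameters for all forms, one row per (form, item) administration.

    Columns of ``table``: global_id, form, position (1-based within form),
    difficulty, discrimination, anchor_pair (pandas NA for unique items),
    anchor_slot (1..9 within the pair's block, NA for unique items).
    Anchor items appear once per form they belong to, with bit-identical
    difficulty and discrimination (measurement invariance).
    """

    table: pd.DataFrame

    def items_for_form(self, timepoint: int) -> pd.DataFrame:
        sub = self.table[self.table["form"] == timepoint]
        if sub.empty:
            raise ConfigurationError(f"no items for form t{timepoint}")
        return sub.sort_values("position").reset_index(drop=True)

    @property
    def forms(self) -> list[int]:
        return sorted(self.table["form"].unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        table = pd.read_csv(path, dtype={"global_id": str})
        for col in ("anchor_pair", "anchor_slot"):
            table[col] = table[col].astype("Int64")
        return cls(table)


def build_item_banks(design: StudyDesign, rng: np.random.Generator) -> ItemBank:
    """Draw a fresh item bank for the four-form design.

    Unique items of form t are drawn from N(true_means[t], 1); the 9-slot
    anchor block shared by forms (t, t+1) is drawn from a normal centred at
    the midpoint of the two adjacent means (unit variance), so anchors target
    both distributions they serve.  Each anchor reuses a single parameter draw
    in both of its forms.  Difficulties are drawn as independent univariate
    normals per item.  With ``misfit`` off every discrimination is exactly 1;
    with it on, discriminations are i.i.d. N(1, alpha_sd^2) truncated below at
    ``alpha_floor``.
    """
    T = design.n_timepoints

    def draw_alphas(n: int) -> np.ndarray:
        if not design.misfit:
            return np.ones(n)
        a = rng.normal(1.0, design.alpha_sd, size=n)
        # balanced moderate misfit: standardize each draw group (anchor block
        # or a form's unique items) to mean exactly 1 and SD alpha_sd, so no
        # form is systematically more or less discriminating than another and
        # misfit distorts item-level, not form-level, measurement
        a = 1.0 + (a - a.mean()) * (design.alpha_sd / max(a.std(), 1e-12))
        return np.maximum(a, design.alpha_floor)

    # one shared draw per anchor, reused in both member forms
    anchor_params: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for pair in range(1, T):
        mid = 0.5 * (design.true_means[pair - 1] + design.true_means[pair])
        deltas = rng.normal(mid, 1.0, size=N_ANCHOR_SLOTS)
        anchor_params[pair] = (deltas, draw_alphas(N_ANCHOR_SLOTS))

    rows = []
    for t in range(1, T + 1):
        position = 1
        for pair in (t - 1, t):  # block shared with previous / next form
            if pair < 1 or pair >= T:
                continue
            deltas, alphas = anchor_params[pair]
            for slot in range(1, N_ANCHOR_SLOTS + 1):
                rows.append(
                    dict(
                        global_id=f"a{pair}_{slot}",
                        form=t,
                        position=position,
                        difficulty=deltas[slot - 1],
                        discrimination=alphas[slot - 1],
                        anchor_pair=pair,
                        anchor_slot=slot,
                    )
                )
                position += 1
        n_unique = design.n_unique_items(t)
        deltas = rng.normal(design.true_means[t - 1], 1.0, size=n_unique)
        alphas = draw_alphas(n_unique)
        for j in range(n_unique):
            rows.append(
                dict(
                    global_id=f"u{t}_{j + 1}",
                    form=t,
                    position=position,
                    difficulty=deltas[j],
                    discrimination=alphas[j],
                    anchor_pair=pd.NA,
                    anchor_slot=pd.NA,
                )
            )
            position += 1

    table = pd.DataFrame(rows)
    table["anchor_pair"] = table["anchor_pair"].astype("Int64")
    table["anchor_slot"] = table["anchor_slot"].astype("Int64")
    return ItemBank(table)


def select_anchors(bank: ItemBank, anchor_count: int, pair: int) -> frozenset[str]:
    """Global ids of the anchor slots used under an anchor-count condition.

    ``pair`` t links forms (t, t+1).  The slot positions are fixed per
    condition (e.g. 3 anchors always occupy slots 2, 5 and 8).
    """
    key = (anchor_count, pair)
    if key not in ANCHOR_POSITIONS:
        raise ConfigurationError(
            f"unknown anchor condition: count={anchor_count}, pair={pair}"
        )
    slots = ANCHOR_POSITIONS[key]
    sub = bank.table[(bank.table["anchor_pair"] == pair)]
    ids = frozenset(sub[sub["anchor_slot"].isin(slots)]["global_id"])
    if len(ids) != len(slots):
        raise ConfigurationError(
            f"bank does not contain all anchor slots for pair {pair}"
        )
    return ids


def restrict_anchors(
    bank: ItemBank, anchor_count: int
) -> tuple[ItemBank, dict[int, frozenset[str]]]:
    """Apply an anchor-count condition to a full 9-slot bank.

    All 25 items per form are still administered, but only the selected slots
    remain common items: unselected anchor slots are relabelled as form-unique
    items (fresh global ids per form, identical parameter values), so form
    length and targeting are constant across conditions and only the amount of
    linking information varies.
    """
    table = bank.table.copy()
    anchor_sets: dict[int, frozenset[str]] = {}
    pairs = sorted(p for p in table["anchor_pair"].dropna().unique())
    for pair in pairs:
        anchor_sets[int(pair)] = select_anchors(bank, anchor_count, int(pair))
    keep = set().union(*anchor_sets.values()) if anchor_sets else set()
    demote = table["anchor_pair"].notna() & ~table["global_id"].isin(keep)
    table.loc[demote, "global_id"] = (
        table.loc[demote, "global_id"] + "@t" + table.loc[demote, "form"].astype(str)
    )
    table.loc[demote, "anchor_pair"] = pd.NA
    table.loc[demote, "anchor_slot"] = pd.NA
    return ItemBank(table), anchor_sets


# ---------------------------------------------------------------------------
# persons and responses
# ---------------------------------------------------------------------------

def draw_abilities(
    design: StudyDesign, timepoint: int, rng: np.random.Generator
) -> np.ndarray:
    """N i.i.d. ability draws from the time point's latent normal."""
    if not 1 <= timepoint <= design.n_timepoints:
        raise ConfigurationError(f"timepoint {timepoint} outside 1..{design.n_timepoints}")
    mean = design.true_means[timepoint - 1]
    sd = float(np.sqrt(design.true_variances[timepoint - 1]))
    return rng.normal(mean, sd, size=design.sample_size)


@dataclass
class ResponseMatrix:
    """Dichotomous persons x items responses for one form at one time point."""

    items: list[str]
    data: np.ndarray  # (N, I) of 0/1, int8
    timepoint: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.items):
            raise ValueError("response data must be (n_persons, n_items)")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("responses must be dichotomous 0/1")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.items)
        df.insert(0, "person_id", np.arange(self.n_persons))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, timepoint: int | None = None) -> "ResponseMatrix":
        df = pd.read_csv(path)
        items = [c for c in df.columns if c != "person_id"]
        return cls(items=items, data=df[items].to_numpy(), timepoint=timepoint)


def simulate_responses(
    abilities: np.ndarray,
    form_items: pd.DataFrame,
    rng: np.random.Generator,
    timepoint: int | None = None,
) -> ResponseMatrix:
    """Bernoulli response sampling, cell-independent given the parameters.

    ``form_items`` is an item table slice with columns global_id, difficulty
    and discrimination (as returned by :meth:`ItemBank.items_for_form`).
    """
    if len(form_items) == 0:
        raise ConfigurationError("cannot simulate responses without items")
    beta = np.asarray(abilities, dtype=float)
    delta = form_items["difficulty"].to_numpy(dtype=float)
    alpha = form_items["discrimination"].to_numpy(dtype=float)
    items = list(form_items["global_id"])
    if beta.size == 0:
        return ResponseMatrix(items=items, data=np.empty((0, len(items)), dtype=np.int8),
                              timepoint=timepoint)
    p = twopl_probability(beta[:, None], delta[None, :], alpha[None, :])
    data = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix(items=items, data=data, timepoint=timepoint)
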