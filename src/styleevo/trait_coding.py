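"""Deterministic binary coding of floral traits and pollination systems.

Floral traits are collapsed to presence/absence scores with fixed,
configurable thresholds: perianth or filament fusion above 5% of the organ
length counts as fused; more than 10 fertile stamens or more than 5
structural carpels counts as "many".  Thresholds are strict on the state-1
side ("greater than"/"more than"); exact boundary values code 0.

Pollinator functional types come from a controlled vocabulary.  Birds and
long-tongued bees (Apidae, Megachilidae), long-tongued flies (Bombyliidae,
Nemestrinidae), butterflies and moths count as long-tongued; every other
animal is short-tongued.  A pollination system is generalist when no
functional type accounts for more than 66% of visits.  Six binary contrasts
are derivable per species: biotic/abiotic, insect/vertebrate, insect/bird,
generalist/specialist, long/short-tongued animals, long/short-tongued
insects; species outside a contrast are set missing.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FUSION_THRESHOLD_PERCENT",
    "STAMEN_THRESHOLD",
    "CARPEL_THRESHOLD",
    "GENERALIST_THRESHOLD",
    "SYSTEM_PAIRS",
    "code_fusion",
    "code_symmetry",
    "code_stamens",
    "code_carpels",
    "code_tongue",
    "code_generalism",
    "normalize_type",
    "build_system_pair",
    "genus_table",
    "code_polymorphism",
]

FUSION_THRESHOLD_PERCENT = 5.0
STAMEN_THRESHOLD = 10
CARPEL_THRESHOLD = 5
GENERALIST_THRESHOLD = 0.66

FUSION_KINDS = ("perianth", "filament", "filament_to_perianth")

# ---------------------------------------------------------------------------
# Controlled vocabulary for pollinator functional types

LONG_TONGUED = frozenset(
    {"bird", "apidae", "megachilidae", "bombyliidae", "nemestrinidae",
     "butterfly", "moth"}
)
BIRDS = frozenset({"bird"})
NON_BIRD_VERTEBRATES = frozenset({"bat", "rodent", "lizard", "marsupial"})
INSECTS = frozenset(
    {"apidae", "megachilidae", "halictidae", "andrenidae", "colletidae",
     "melittidae", "bombyliidae", "nemestrinidae", "syrphidae", "muscidae",
     "butterfly", "moth", "beetle", "wasp", "ant", "thrips", "fly"}
)
ABIOTIC = frozenset({"wind", "water"})
VOCABULARY = LONG_TONGUED | BIRDS | NON_BIRD_VERTEBRATES | INSECTS | ABIOTIC

_SYNONYMS = {
    "hummingbird": "bird",
    "sunbird": "bird",
    "birds": "bird",
    "nemestridae": "nemestrinidae",  # spelling variant in the literature
    "lepidoptera-butterfly": "butterfly",
    "butterflies": "butterfly",
    "moths": "moth",
    "sphingidae": "moth",
    "bats": "bat",
    "beetles": "beetle",
    "coleoptera": "beetle",
    "wasps": "wasp",
    "hymenoptera-wasp": "wasp",
    "flies": "fly",
    "diptera": "fly",
}


def normalize_type(functional_type: str) -> str:
    """Case-fold and resolve synonyms; unknown terms are errors, never a
    silent 'short'."""
    t = str(functional_type).strip().casefold()
    t = _SYNONYMS.get(t, t)
    if t not in VOCABULARY:
        raise ValueError(f"unknown pollinator functional type {functional_type!r}")
    return t


def is_animal(t: str) -> bool:
    return normalize_type(t) not in ABIOTIC


def is_insect(t: str) -> bool:
    return normalize_type(t) in INSECTS


def is_vertebrate(t: str) -> bool:
    t = normalize_type(t)
    return t in BIRDS or t in NON_BIRD_VERTEBRATES


# ---------------------------------------------------------------------------
# Floral trait coding


def code_fusion(
    percent_fused: float,
    kind: str = "perianth",
    threshold: float = FUSION_THRESHOLD_PERCENT,
) -> int:
    """1 (fused) iff the fused fraction exceeds the threshold (% of organ
    length); exact boundary values code 0 (unfused)."""
    if kind not in FUSION_KINDS:
        raise ValueError(f"unknown fusion kind {kind!r}")
    p = float(percent_fused)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent fused {p} outside [0, 100]")
    return int(p > threshold)


def code_symmetry(symmetry_class: str) -> int:
    """Actinomorphic -> 0, zygomorphic -> 1 (case-insensitive)."""
    c = str(symmetry_class).strip().casefold()
    if c == "actinomorphic":
        return 0
    if c == "zygomorphic":
        return 1
    raise ValueError(f"unknown perianth symmetry class {symmetry_class!r}")


def code_stamens(n: int, threshold: int = STAMEN_THRESHOLD) -> int:
    """0 for up to ``threshold`` fertile stamens, 1 for more."""
    n = int(n)
    if n < 0:
        raise ValueError("stamen count must be non-negative")
    return int(n > threshold)


def code_carpels(n: int, threshold: int = CARPEL_THRESHOLD) -> int:
    """0 for up to ``threshold`` structural carpels, 1 for more."""
    n = int(n)
    if n < 0:
        raise ValueError("carpel count must be non-negative")
    return int(n > threshold)


# ---------------------------------------------------------------------------
# Pollination system coding


def code_tongue(functional_type: str) -> str:
    """'long' or 'short' for an animal functional type; abiotic types are
    rejected (they have no tongue class and are handled by the contrast
    pairing)."""
    t = normalize_type(functional_type)
    if t in ABIOTIC:
        raise ValueError(f"abiotic type {functional_type!r} has no tongue class")
    return "long" if t in LONG_TONGUED else "short"


def code_generalism(
    visit_fractions: Mapping[str, float], threshold: float = GENERALIST_THRESHOLD
) -> str:
    """'generalist' iff no functional type exceeds ``threshold`` of visits
    (strictly more than 66% makes a specialist)."""
    fracs = {normalize_type(k): float(v) for k, v in visit_fractions.items()}
    if any(v < 0 for v in fracs.values()):
        raise ValueError("visit fractions must be non-negative")
    if not fracs or all(v == 0 for v in fracs.values()):
        raise ValueError("all-zero visit fractions")
    return "generalist" if max(fracs.values()) <= threshold else "specialist"


SYSTEM_PAIRS = (
    "biotic_vs_abiotic",
    "insect_vs_vertebrate",
    "insect_vs_bird",
    "generalist_vs_specialist",
    "long_vs_short_tongued_animals",
    "long_vs_short_tongued_insects",
)


def _dominant_type(group: pd.DataFrame) -> str:
    """Functional type with the largest visit fraction (ties: first in
    sorted order, deterministic)."""
    g = group.sort_values(["fraction", "pollinator_type"], ascending=[False, True])
    return normalize_type(g.iloc[0]["pollinator_type"])


def build_system_pair(records: pd.DataFrame, pair: str) -> pd.DataFrame:
    """Binary coding of one pollination-system contrast.

    ``records`` is a long table with columns ``species``, ``pollinator_type``
    and ``fraction`` (visit fractions per functional type; a single record
    with fraction 1.0 denotes a known single system).  Returns one row per
    species with columns ``species``, ``state`` (0 = left term of the
    contrast name, 1 = right term, NaN = not scorable) plus the dominant
    type; exclusion counts are attached as ``DataFrame.attrs['n_excluded']``.
    """
    if pair not in SYSTEM_PAIRS:
        raise ValueError(f"unknown system pair {pair!r}; choose from {SYSTEM_PAIRS}")
    required = {"species", "pollinator_type", "fraction"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")

    rows = []
    for species, group in records.groupby("species", sort=True):
        dom = _dominant_type(group)
        state: float
        if pair == "biotic_vs_abiotic":
            state = 1 if dom in ABIOTIC else 0
        elif pair == "insect_vs_vertebrate":
            if dom in ABIOTIC:
                state = np.nan
            else:
                state = 1 if is_vertebrate(dom) else 0
        elif pair == "insect_vs_bird":
            if dom in BIRDS:
                state = 1
            elif dom in INSECTS:
                state = 0
            else:
                state = np.nan
        elif pair == "generalist_vs_specialist":
            if dom in ABIOTIC:
                state = np.nan
            else:
                fr = dict(zip(group["pollinator_type"], group["fraction"]))
                state = 0 if code_generalism(fr) == "generalist" else 1
        elif pair == "long_vs_short_tongued_animals":
            if dom in ABIOTIC:
                state = np.nan
            else:
                state = 0 if code_tongue(dom) == "long" else 1
        else:  # long_vs_short_tongued_insects
            if dom in INSECTS:
                state = 0 if code_tongue(dom) == "long" else 1
            else:
                state = np.nan
        rows.append({"species": species, "state": state, "dominant_type": dom})
    out = pd.DataFrame(rows)
    out.attrs["pair"] = pair
    out.attrs["n_excluded"] = int(out["state"].isna().sum())
    return out


# ---------------------------------------------------------------------------
# Genus-level assembly


def code_polymorphism(
    reports: pd.DataFrame, include_doubtful: bool = False
) -> pd.Series:
    """Genus -> 1 for any qualifying style-length polymorphism report.

    ``reports`` has columns ``genus``, ``evidence`` (mention | description |
    statistical_test) and optionally ``doubtful`` (bool).  Doubtful reports
    are excluded unless ``include_doubtful``.
    """
    df = reports.copy()
    if "doubtful" in df.columns and not include_doubtful:
        df = df[~df["doubtful"].astype(bool)]
    coded = df.groupby("genus").size() > 0
    return coded.astype(int)


def genus_table(
    species_table: pd.DataFrame, seed: int, genus_column: str = "genus"
) -> pd.DataFrame:
    """Collapse a species-level trait table to one species per genus.

    The representative species is drawn with ``numpy.random.default_rng``
    over genera and members in sorted order, so the result is a
    deterministic function of (table, seed).
    """
    if genus_column not in species_table.columns:
        raise ValueError(f"missing {genus_column!r} column")
    rng = np.random.default_rng(seed)
    picks = []
    df = species_table.sort_values(["species"]).reset_index(drop=True)
    for genus in sorted(df[genus_column].unique()):
        members = df.index[df[genus_column] == genus].to_numpy()
        picks.append(members[rng.integers(len(members))])
    out = df.loc[picks].reset_index(drop=True)
    out.attrs["seed"] = seed
    return out
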