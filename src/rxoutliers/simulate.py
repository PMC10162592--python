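"""Synthetic NHSBSA-style prescribing extracts with planted outliers.

The generator emulates the *shape* of the public English prescribing
extract — practice-level monthly item counts over a chemical catalogue
organised into subparagraphs, with a four-level administrative hierarchy
and heavy-tailed practice volumes — so the whole pipeline is testable
without downloading anything.

Model: for each practice, subparagraph and month, a proportion vector
over the subparagraph's chemicals is drawn from a Dirichlet distribution
centred on the catalogue baseline (``Dirichlet(concentration * baseline)``,
larger concentration = less between-practice dispersion), planted odds
shifts are applied, a total subparagraph volume is drawn log-normally and
rounded, and items are allocated multinomially among the chemicals (then
split across a couple of presentation-level codes).  This
Dirichlet-multinomial structure is the minimal generator producing
compositional counts with tunable between-organisation dispersion — the
structure the z-score statistic assumes — and is not claimed to be the
mechanism of real prescribing data.

A truth table records every planted anomaly so recovery tests need no
re-derivation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bnf
from .ingest import CountMatrix, StudyWindow

__all__ = [
    "Chemical",
    "Subparagraph",
    "PlantedOutlier",
    "SimulationConfig",
    "SimulatedDataset",
    "default_catalogue",
    "default_config",
    "generate",
    "write_dataset",
    "devon_fixture",
    "devon_name_lookup",
]


@dataclass(frozen=True)
class Chemical:
    code: str
    name: str


@dataclass(frozen=True)
class Subparagraph:
    """A drug class: its 7-character code, member chemicals and the
    national baseline proportion vector over those chemicals."""

    code: str
    name: str
    chemicals: tuple[Chemical, ...]
    baseline: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.chemicals) < 2:
            raise ValueError(f"subparagraph {self.code} needs >= 2 chemicals")
        if len(self.baseline) != len(self.chemicals):
            raise ValueError("baseline length must match chemical count")
        if abs(sum(self.baseline) - 1.0) > 1e-9:
            raise ValueError(f"baseline of {self.code} must sum to 1")
        for chem in self.chemicals:
            bnf.validate_code(chem.code)
            if not chem.code.startswith(self.code):
                raise ValueError(
                    f"chemical {chem.code} does not extend subparagraph {self.code}"
                )


@dataclass(frozen=True)
class PlantedOutlier:
    """A practice whose true proportion of one chemical is shifted.

    ``magnitude`` is a multiplicative odds shift (> 1): for direction
    "higher" the chemical's odds p/(1-p) are multiplied by it, for
    "lower" divided; the rest of the vector is renormalised.
    """

    practice_code: str
    chemical_code: str
    direction: str = "higher"
    magnitude: float = 3.0

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"direction must be higher/lower, got {self.direction!r}")
        if not self.magnitude > 1.0:
            raise ValueError("magnitude must be > 1 (a no-op outlier is rejected)")


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic extract.

    Tree shape defaults to 2 STPs x 2 CCGs x 3 PCNs x 5 practices
    (60 typical practices) over a catalogue of 10 subparagraphs of 4
    chemicals, for the 6 months from June 2021 — a desk-scale analogue
    of the national data's structure.  ``concentration`` sets the
    Dirichlet dispersion (50 gives a realistic few-percentage-point
    between-practice spread); volumes are log-normal with the given log
    mean/SD (defaults give a median of ~150 items per practice,
    subparagraph and month, with a heavy right tail).
    """

    n_stp: int = 2
    n_ccg_per_stp: int = 2
    n_pcn_per_ccg: int = 3
    n_practice_per_pcn: int = 5
    catalogue: tuple[Subparagraph, ...] = ()
    concentration: float = 50.0
    volume_log_mean: float = 5.0
    volume_log_sd: float = 0.5
    n_months: int = 6
    start_month: str = "2021-06"
    n_presentations: int = 2
    n_atypical_practices: int = 2
    planted: tuple[PlantedOutlier, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.catalogue:
            self.catalogue = default_catalogue()
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        chem_codes = {c.code for s in self.catalogue for c in s.chemicals}
        for p in self.planted:
            if p.chemical_code not in chem_codes:
                raise ValueError(
                    f"planted chemical {p.chemical_code!r} not in catalogue"
                )

    @property
    def window(self) -> StudyWindow:
        start = pd.Period(self.start_month, freq="M")
        return StudyWindow.from_strings(
            str(start), str(start + self.n_months)
        )


def default_catalogue(
    n_subparagraphs: int = 10, n_chemicals: int = 4
) -> tuple[Subparagraph, ...]:
    """A deterministic synthetic catalogue.

    Subparagraph ``i`` sits in chapter ``(i mod 15) + 1`` with code
    ``{chapter:02d}{i:02d}010`` and chemicals lettered A, B, C, ...
    Baseline proportions fall geometrically (each chemical half as common
    as the one before), mimicking a class with a dominant first-line drug.
    """
    weights = np.array([2.0 ** -i for i in range(n_chemicals)])
    baseline = tuple(weights / weights.sum())
    subs = []
    for i in range(n_subparagraphs):
        chapter = (i % 15) + 1
        code = f"{chapter:02d}{i:02d}010"
        chems = tuple(
            Chemical(
                code=f"{code}{string.ascii_uppercase[j]}0",
                name=f"Chemical {code}{string.ascii_uppercase[j]}",
            )
            for j in range(n_chemicals)
        )
        subs.append(
            Subparagraph(
                code=code,
                name=f"Drug class {code}",
                chemicals=chems,
                baseline=baseline,
            )
        )
    return tuple(subs)


def default_config(
    seed: int = 0, planted: tuple[PlantedOutlier, ...] = ()
) -> SimulationConfig:
    return SimulationConfig(seed=seed, planted=tuple(planted))


def example_planted(
    config: SimulationConfig | None = None,
    magnitude: float = 3.0,
    direction: str = "higher",
) -> PlantedOutlier:
    """A canonical planted outlier: the first typical practice prescribes
    the catalogue's first second-line chemical far more than peers."""
    cat = (config.catalogue if config else None) or default_catalogue()
    return PlantedOutlier(
        practice_code="P00001",
        chemical_code=cat[0].chemicals[1].code,
        direction=direction,
        magnitude=magnitude,
    )


@dataclass
class SimulatedDataset:
    register: pd.DataFrame  # org_code, name, level, is_typical
    mapping: pd.DataFrame  # practice_code, pcn_code, ccg_code, stp_code
    records: pd.DataFrame  # PRACTICE_CODE, BNF_CODE, ITEMS, YEAR_MONTH
    truth: pd.DataFrame  # practice_code, chemical_code, direction, magnitude
    config: SimulationConfig
    #: drawn totals per practice/subparagraph/month, for conservation checks
    volumes: pd.DataFrame | None = None


def _build_orgs(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    register_rows = []
    mapping_rows = []
    practices: list[str] = []
    p = 0
    pcn_i = 0
    ccg_i = 0
    for s in range(cfg.n_stp):
        stp = f"STP{s + 1:02d}"
        register_rows.append((stp, f"Sustainability partnership {s + 1}", "stp", ""))
        for _c in range(cfg.n_ccg_per_stp):
            ccg_i += 1
            ccg = f"CCG{ccg_i:03d}"
            register_rows.append((ccg, f"Commissioning group {ccg_i}", "ccg", ""))
            for _n in range(cfg.n_pcn_per_ccg):
                pcn_i += 1
                pcn = f"PCN{pcn_i:03d}"
                register_rows.append((pcn, f"Care network {pcn_i}", "pcn", ""))
                for _k in range(cfg.n_practice_per_pcn):
                    p += 1
                    prac = f"P{p:05d}"
                    practices.append(prac)
                    register_rows.append((prac, f"Practice {p}", "practice", "True"))
                    mapping_rows.append((prac, pcn, ccg, stp))
    # atypical practices (prison / specialist clinics); attached to the
    # first branch, excluded by the typicality filter downstream
    atypical: list[str] = []
    for a in range(cfg.n_atypical_practices):
        p += 1
        prac = f"P{p:05d}"
        atypical.append(prac)
        register_rows.append((prac, f"Specialist clinic {a + 1}", "practice", "False"))
        mapping_rows.append((prac, "PCN001", "CCG001", "STP01"))
    register = pd.DataFrame(
        register_rows, columns=["org_code", "name", "level", "is_typical"]
    )
    mapping = pd.DataFrame(
        mapping_rows, columns=["practice_code", "pcn_code", "ccg_code", "stp_code"]
    )
    return register, mapping, practices + atypical


def _apply_odds_shift(
    props: np.ndarray, j: int, magnitude: float, direction: str
) -> np.ndarray:
    """Shift chemical ``j``'s proportion by a multiplicative odds factor
    on each row of ``props`` and renormalise the remaining chemicals."""
    out = props.copy()
    p = out[:, j]
    odds = p / np.clip(1.0 - p, 1e-12, None)
    odds = odds * magnitude if direction == "higher" else odds / magnitude
    p_new = odds / (1.0 + odds)
    scale = (1.0 - p_new) / np.clip(1.0 - p, 1e-12, None)
    out *= scale[:, None]
    out[:, j] = p_new
    return out / out.sum(axis=1, keepdims=True)


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a fully reproducible synthetic extract.

    The same config (including seed) always yields identical tables; the
    PRNG is numpy's seeded PCG64 so results are stable across platforms.
    """
    rng = np.random.default_rng(config.seed)
    register, mapping, practices = _build_orgs(config)

    start = pd.Period(config.start_month, freq="M")
    months = [(start + m).strftime("%Y%m") for m in range(config.n_months)]

    planted_by_practice: dict[str, list[PlantedOutlier]] = {}
    for po in config.planted:
        planted_by_practice.setdefault(po.practice_code, []).append(po)

    pres_suffixes = [f"AAAA{t:02d}" for t in range(config.n_presentations)]
    pres_weights = np.array(
        [2.0 ** -t for t in range(config.n_presentations)], dtype=float
    )
    pres_weights /= pres_weights.sum()

    rows_practice: list[str] = []
    rows_code: list[str] = []
    rows_items: list[int] = []
    rows_month: list[str] = []
    volume_rows: list[tuple[str, str, str, int]] = []

    for practice in practices:
        shifts = {
            po.chemical_code: po for po in planted_by_practice.get(practice, [])
        }
        for sub in config.catalogue:
            alpha = config.concentration * np.asarray(sub.baseline)
            props = rng.dirichlet(alpha, size=config.n_months)
            for j, chem in enumerate(sub.chemicals):
                if chem.code in shifts:
                    po = shifts[chem.code]
                    props = _apply_odds_shift(props, j, po.magnitude, po.direction)
            volumes = np.rint(
                rng.lognormal(
                    config.volume_log_mean, config.volume_log_sd, config.n_months
                )
            ).astype(int)
            for m, month in enumerate(months):
                volume_rows.append((practice, sub.code, month, int(volumes[m])))
                counts = rng.multinomial(volumes[m], props[m])
                for j, chem in enumerate(sub.chemicals):
                    if counts[j] == 0:
                        continue
                    split = rng.multinomial(counts[j], pres_weights)
                    for t, n_items in enumerate(split):
                        if n_items == 0:
                            continue
                        rows_practice.append(practice)
                        rows_code.append(chem.code + pres_suffixes[t])
                        rows_items.append(int(n_items))
                        rows_month.append(month)

    records = pd.DataFrame(
        {
            "PRACTICE_CODE": rows_practice,
            "BNF_CODE": rows_code,
            "ITEMS": rows_items,
            "YEAR_MONTH": rows_month,
        }
    )
    truth = pd.DataFrame(
        [
            (po.practice_code, po.chemical_code, po.direction, po.magnitude)
            for po in config.planted
        ],
        columns=["practice_code", "chemical_code", "direction", "magnitude"],
    )
    volumes = pd.DataFrame(
        volume_rows,
        columns=["practice_code", "subparagraph_code", "month", "volume"],
    )
    return SimulatedDataset(
        register=register,
        mapping=mapping,
        records=records,
        truth=truth,
        config=config,
        volumes=volumes,
    )


def name_lookup(config: SimulationConfig) -> pd.DataFrame:
    """Chemical/subparagraph name table for a config's catalogue."""
    rows = [
        (c.code, c.name, s.code, s.name)
        for s in config.catalogue
        for c in s.chemicals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chemical_code",
            "chemical_name",
            "subparagraph_code",
            "subparagraph_name",
        ],
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write the dataset as the CSV dialects the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescribing": out / "prescribing.csv",
        "register": out / "register.csv",
        "mapping": out / "mapping.csv",
        "truth": out / "truth.csv",
        "names": out / "names.csv",
    }
    ds.records.to_csv(paths["prescribing"], index=False, lineterminator="\n")
    ds.register.to_csv(paths["register"], index=False, lineterminator="\n")
    ds.mapping.to_csv(paths["mapping"], index=False, lineterminator="\n")
    ds.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    name_lookup(ds.config).to_csv(paths["names"], index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# Worked-example fixture: the published NHS Devon CCG dashboard counts.
# ---------------------------------------------------------------------------

# (chemical name, n_products, chemical items, subparagraph name,
#  subparagraph items, side) as printed in the published CCG dashboard.
# The pseudo-BNF codes below are synthetic stand-ins (the published table
# prints names, not codes) chosen to respect the 7/9-character prefix
# convention and to share a single code per subparagraph.
_DEVON_SUBPARAGRAPHS = {
    "Local anesthetics": "1502010",
    "Sodium bicarbonate": "0105000",
    "Foods for special diets": "0904010",
    "Hypoplastic, hemolytic, and renal anemias": "0901030",
    "Otitis externa": "1201010",
    "Quinolones": "0501120",
    "Phenolics": "1104060",
    "Other antineoplastic drugs": "0801050",
    "Oral iron": "0901011",
    "Antihistamines": "0304010",
    "Oral sodium and water": "0902011",
    "Topical corticosteroids": "1304000",
    "Antibacterials": "1310010",
    "Stimulant laxatives": "0106020",
    "Antiplatelet drugs": "0209000",
    "Osmotic laxatives": "0106040",
}

_DEVON_ROWS = [
    # higher than most
    ("Levobupivacaine hydrochloride", "L0", 1, 130, "Local anesthetics", 20482, "higher"),
    ("Gripe mixtures", "G0", 1, 1, "Sodium bicarbonate", 56, "higher"),
    ("Gluten free pastas", "P0", 3, 4, "Foods for special diets", 9199, "higher"),
    ("Epoetin zeta", "Z0", 1, 2, "Hypoplastic, hemolytic, and renal anemias", 18, "higher"),
    ("Flumetasone pivalate", "F0", 1, 333, "Otitis externa", 19724, "higher"),
    ("Gluten free or wheat free cereals", "C0", 1, 2, "Foods for special diets", 9199, "higher"),
    ("Levofloxacin", "L0", 2, 1372, "Quinolones", 4754, "higher"),
    ("Liquefied phenol", "P0", 1, 1, "Phenolics", 3, "higher"),
    ("Ruxolitinib", "R0", 1, 2, "Other antineoplastic drugs", 1494, "higher"),
    ("Ferrous gluconate", "F0", 1, 10437, "Oral iron", 90095, "higher"),
    # lower than most
    ("Sodium bicarbonate", "S0", 3, 55, "Sodium bicarbonate", 56, "lower"),
    ("Ciprofloxacin", "C0", 6, 2989, "Quinolones", 4754, "lower"),
    ("Dexamethasone", "D0", 2, 13061, "Otitis externa", 19724, "lower"),
    ("Fexofenadine hydrochloride", "F0", 6, 33711, "Antihistamines", 169747, "lower"),
    ("Oral rehydration salts", "O0", 8, 1942, "Oral sodium and water", 5010, "lower"),
    ("Betamethasone esters", "B0", 12, 1672, "Topical corticosteroids", 141063, "lower"),
    ("Fusidic acid", "F0", 1, 359, "Antibacterials", 13283, "lower"),
    ("Senna", "S0", 9, 39769, "Stimulant laxatives", 110838, "lower"),
    ("Ticagrelor", "T0", 3, 2285, "Antiplatelet drugs", 467104, "lower"),
    ("Lactulose", "L0", 2, 19621, "Osmotic laxatives", 127773, "lower"),
]

DEVON_ORG_CODE = "DEVON"

#: printed ratio, to 2 decimals, for each fixture chemical name
DEVON_PRINTED_RATIOS = {
    "Levobupivacaine hydrochloride": 0.01,
    "Gripe mixtures": 0.02,
    "Gluten free pastas": 0.00,
    "Epoetin zeta": 0.11,
    "Flumetasone pivalate": 0.02,
    "Gluten free or wheat free cereals": 0.00,
    "Levofloxacin": 0.29,
    "Liquefied phenol": 0.33,
    "Ruxolitinib": 0.00,
    "Ferrous gluconate": 0.12,
    "Sodium bicarbonate": 0.98,
    "Ciprofloxacin": 0.63,
    "Dexamethasone": 0.66,
    "Fexofenadine hydrochloride": 0.20,
    "Oral rehydration salts": 0.39,
    "Betamethasone esters": 0.01,
    "Fusidic acid": 0.03,
    "Senna": 0.36,
    "Ticagrelor": 0.00,
    "Lactulose": 0.15,
}


def _devon_frame() -> pd.DataFrame:
    rows = []
    for name, suffix, n_products, chem_items, sub_name, sub_items, side in _DEVON_ROWS:
        sub_code = _DEVON_SUBPARAGRAPHS[sub_name]
        rows.append(
            {
                "org_code": DEVON_ORG_CODE,
                "chemical_code": sub_code + suffix,
                "chemical_name": name,
                "chemical_items": chem_items,
                "n_products": n_products,
                "subparagraph_code": sub_code,
                "subparagraph_name": sub_name,
                "subparagraph_items": sub_items,
                "side": side,
            }
        )
    df = pd.DataFrame(rows)
    if df["chemical_code"].duplicated().any():
        raise AssertionError("fixture chemical codes must be unique")
    return df


def devon_fixture() -> CountMatrix:
    """The published NHS Devon CCG dashboard counts as a CountMatrix.

    A single-organisation matrix holding exactly the 20 printed
    (chemical, chemical items, subparagraph, subparagraph items) tuples
    of the dashboard's higher/lower tables.  The denominators are the
    published whole-subparagraph totals (the table lists only the 20
    extreme chemicals, so they exceed the listed chemicals' sums).
    """
    df = _devon_frame()
    frame = df[
        [
            "org_code",
            "chemical_code",
            "chemical_items",
            "n_products",
            "subparagraph_code",
            "subparagraph_items",
        ]
    ].copy()
    return CountMatrix(
        level="ccg",
        frame=frame,
        window=StudyWindow.from_strings("2021-06", "2021-12"),
    )


def devon_name_lookup() -> pd.DataFrame:
    """Name lookup matching :func:`devon_fixture`'s synthetic codes."""
    df = _devon_frame()
    return df[
        ["chemical_code", "chemical_name", "subparagraph_code", "subparagraph_name"]
    ].copy()
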