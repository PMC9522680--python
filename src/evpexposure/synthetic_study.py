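"""Synthetic exhaled-breath crossover study generator.

Emulates a four-way, four-sequence (Williams-square style) crossover in which
each subject uses one e-vapor product (EVP) per period and provides, per
period, a paired sham (empty cartridge, dead battery) and product
exhaled-breath collection.  Two trapping-container types split the analytes:
collection 1 captures nicotine, propylene glycol, glycerin and menthol;
collection 2 captures formaldehyde, acetaldehyde and acrolein.

Measured masses are in µg per 10-puff session.  Values below the analytical
minimum detectable level (MDL) are replaced by the MDL and flagged, mirroring
standard left-censoring substitution in exposure analytics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Product",
    "StudyDesign",
    "GenerationParams",
    "apply_mdl_censoring",
    "generate_study",
    "SESSION_COLUMNS",
]

#: analyte -> trapping-container collection type
COLLECTION_OF = {
    "nicotine": 1,
    "propylene_glycol": 1,
    "glycerin": 1,
    "menthol": 1,
    "formaldehyde": 2,
    "acetaldehyde": 2,
    "acrolein": 2,
}

SESSION_COLUMNS = [
    "subject_id",
    "sequence",
    "period",
    "product",
    "collection",
    "analyte",
    "sham_value_ug",
    "product_value_ug",
    "censored_sham",
    "censored_product",
    "consumed_mg",
]


@dataclass(frozen=True)
class Product:
    """One e-liquid variant loaded in the cartridge-based device."""

    id: str
    nicotine_by_weight: float  # mass fraction, e.g. 0.035 for 3.5%
    mentholated: bool = False


def _default_products() -> tuple[Product, ...]:
    return (
        Product("tp1", 0.025, False),
        Product("tp2", 0.040, False),
        Product("tp3", 0.035, True),
        Product("tp4", 0.040, True),
    )


# sequence letters map A..D onto product list positions
_LETTER_TO_INDEX = {"A": 0, "B": 1, "C": 2, "D": 3}


@dataclass(frozen=True)
class StudyDesign:
    """Crossover layout: who uses which product in which period.

    The default is 32 subjects in four sequences (ABDC, BCAD, CDBA, DACB),
    eight subjects per sequence, four products, seven analytes split across
    the two collection types.
    """

    n_subjects: int = 32
    sequences: tuple[str, ...] = ("ABDC", "BCAD", "CDBA", "DACB")
    subjects_per_sequence: int = 8
    products: tuple[Product, ...] = field(default_factory=_default_products)
    collections: dict[str, int] = field(default_factory=lambda: dict(COLLECTION_OF))

    def __post_init__(self) -> None:
        if self.n_subjects != self.subjects_per_sequence * len(self.sequences):
            raise ValueError(
                "n_subjects must equal subjects_per_sequence x number of sequences"
            )
        n_prod = len(self.products)
        for seq in self.sequences:
            if len(seq) != n_prod or sorted(seq) != sorted(
                "ABCD"[:n_prod]
            ):
                raise ValueError(
                    f"sequence {seq!r} must contain each product letter exactly once"
                )
        for analyte, coll in self.collections.items():
            if coll not in (1, 2):
                raise ValueError(f"unknown collection type {coll} for {analyte!r}")

    @property
    def analytes(self) -> list[str]:
        return list(self.collections)

    def product_for(self, sequence: str, period: int) -> Product:
        """Product used in a 1-based period by a subject on this sequence."""
        return self.products[_LETTER_TO_INDEX[sequence[period - 1]]]


def _table2_means() -> dict[tuple[str, str], float]:
    # per-product true exhaled masses, µg per 10 puffs (sham-corrected scale)
    means = {
        "nicotine": (89.44, 195.70, 168.83, 182.65),
        "propylene_glycol": (1678.4, 1199.7, 3354.5, 2511.0),
        "glycerin": (5972.3, 6099.5, 6484.7, 5366.8),
        "menthol": (0.17, 0.35, 21.11, 31.01),
        "formaldehyde": (0.25, 0.25, 0.34, 0.30),
        "acetaldehyde": (0.0, 0.0, 0.0, 0.0),
        "acrolein": (0.0, 0.0, 0.0, 0.0),
    }
    out: dict[tuple[str, str], float] = {}
    for analyte, vals in means.items():
        for pid, v in zip(("tp1", "tp2", "tp3", "tp4"), vals):
            out[analyte, pid] = v
    return out


def _default_mdl() -> dict[str, float]:
    # MDLs (µg per session) chosen to reproduce the qualitative censoring
    # pattern: menthol censored mostly for non-mentholated products,
    # formaldehyde occasionally, acetaldehyde/acrolein always.
    return {
        "nicotine": 1.0,
        "propylene_glycol": 10.0,
        "glycerin": 10.0,
        "menthol": 1.0,
        "formaldehyde": 0.1,
        "acetaldehyde": 0.5,
        "acrolein": 0.5,
    }


def _default_sham_mean() -> dict[str, float]:
    # sham collections carry no e-liquid; only formaldehyde shows an
    # endogenous-breath background comparable to product sessions
    return {
        "nicotine": 0.0,
        "propylene_glycol": 0.0,
        "glycerin": 0.0,
        "menthol": 0.0,
        "formaldehyde": 0.2,
        "acetaldehyde": 0.0,
        "acrolein": 0.0,
    }


def _default_consumption() -> dict[tuple[str, int], tuple[float, float]]:
    # (product, collection) -> (mean mg, SD mg) of e-liquid consumed in the
    # 10-puff session
    c1 = {"tp1": (35.2, 8.70), "tp2": (33.7, 11.37), "tp3": (40.2, 12.6), "tp4": (36.7, 12.32)}
    c2 = {"tp1": (35.6, 11.53), "tp2": (36.3, 11.94), "tp3": (41.2, 14.58), "tp4": (37.9, 12.4)}
    out: dict[tuple[str, int], tuple[float, float]] = {}
    for pid, ms in c1.items():
        out[pid, 1] = ms
    for pid, ms in c2.items():
        out[pid, 2] = ms
    return out


@dataclass
class GenerationParams:
    """Distributional parameters of the generator.

    Product values are lognormal with a per-subject multiplicative random
    effect shared across that subject's sessions (between-subject CV) and a
    session-level residual (within-subject CV); both lognormals are
    mean-one.  Sham values are lognormal around the sham background.
    Consumption is normal truncated at zero.  ``seed`` makes the whole
    dataset reproducible bit for bit.
    """

    true_mean: dict[tuple[str, str], float] = field(default_factory=_table2_means)
    cv_between: float = 0.6
    cv_within: float = 0.6
    sham_mean: dict[str, float] = field(default_factory=_default_sham_mean)
    mdl: dict[str, float] = field(default_factory=_default_mdl)
    consumption: dict[tuple[str, int], tuple[float, float]] = field(
        default_factory=_default_consumption
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_between < 0 or self.cv_within < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        if any(v < 0 for v in self.true_mean.values()):
            raise ValueError("true means must be nonnegative")
        if any(v < 0 for v in self.sham_mean.values()):
            raise ValueError("sham background means must be nonnegative")
        if any(m <= 0 for m in self.mdl.values()):
            raise ValueError("MDLs must be positive")
        for (pid, coll), (mean, sd) in self.consumption.items():
            if mean <= 0 or sd < 0:
                raise ValueError(
                    f"consumption mean must be > 0 and SD >= 0 for ({pid}, {coll})"
                )


def apply_mdl_censoring(value: float, mdl: float) -> tuple[float, bool]:
    """Left-censor a measurement at the minimum detectable level.

    Values below the MDL are replaced by the MDL and flagged; values at or
    above it pass through unchanged.

    Returns ``(censored_value, was_censored)``.
    """
    if mdl <= 0:
        raise ValueError("mdl must be positive")
    if value < mdl:
        return mdl, True
    return float(value), False


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _lognormal_with_mean(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0.0:
        return 0.0
    return float(mean * _lognormal_mean_one(rng, cv))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero by rejection (fast for mean >> 0)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    # mean/sd would have to be pathological to get here
    raise RuntimeError("truncated-normal sampling failed to find a positive draw")


def generate_study(design: StudyDesign, params: GenerationParams) -> pd.DataFrame:
    """Generate one synthetic crossover dataset.

    Returns a tidy frame with one row per subject x period x analyte (the
    collection type follows the analyte), columns :data:`SESSION_COLUMNS`.
    Each subject's rows are generated from an independent stream keyed by
    ``(seed, subject index)`` so output is identical regardless of subject
    iteration order.
    """
    rows: list[dict] = []
    analytes = design.analytes
    for subj_idx in range(design.n_subjects):
        seq = design.sequences[subj_idx // design.subjects_per_sequence]
        subject_id = f"S{subj_idx + 1:03d}"
        rng = np.random.default_rng([params.seed, subj_idx])
        # subject-level multiplicative effect, one per analyte, shared
        # across this subject's four periods
        subj_effect = {a: float(_lognormal_mean_one(rng, params.cv_between)) for a in analytes}
        for period in range(1, len(design.sequences[0]) + 1):
            product = design.product_for(seq, period)
            consumed = {
                coll: _truncated_normal(rng, *params.consumption[product.id, coll])
                for coll in (1, 2)
            }
            for analyte in analytes:
                coll = design.collections[analyte]
                mean = params.true_mean.get((analyte, product.id), 0.0)
                raw_product = mean * subj_effect[analyte] * float(
                    _lognormal_mean_one(rng, params.cv_within)
                )
                raw_sham = _lognormal_with_mean(
                    rng, params.sham_mean.get(analyte, 0.0), params.cv_within
                )
                mdl = params.mdl[analyte]
                product_value, cens_product = apply_mdl_censoring(raw_product, mdl)
                sham_value, cens_sham = apply_mdl_censoring(raw_sham, mdl)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "sequence": seq,
                        "period": period,
                        "product": product.id,
                        "collection": coll,
                        "analyte": analyte,
                        "sham_value_ug": sham_value,
                        "product_value_ug": product_value,
                        "censored_sham": cens_sham,
                        "censored_product": cens_product,
                        "consumed_mg": consumed[coll],
                    }
                )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)
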