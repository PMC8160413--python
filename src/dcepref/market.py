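"""Multi-product preference-share simulation from part-worth utilities.

A product profile fixes one numeric value per attribute (values may fall
between or outside the design levels; utilities are interpolated on the
attribute's linear or log axis, with linear extrapolation beyond the
boundary levels). A respondent's total product utility is the sum of the
per-attribute utilities. Shares across a competitive set are computed by

* ``logit`` (share of preference): share of product p for respondent i is
  exp(U_ip) normalised over the set, rescaled to sum to 100%; the overall
  share is the mean of the per-respondent shares.
* ``first_choice``: each respondent's share mass goes entirely to their
  highest-utility product.
* ``rfc`` (randomized first choice): first choice tallied over Monte-Carlo
  draws with independent Gumbel perturbations of the product utilities;
  approaches ``first_choice`` as the noise scale shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributes import AttributeSpec, attribute_index
from .partworths import PartWorthSet

__all__ = [
    "ProductProfile",
    "ShareResult",
    "utility_at_value",
    "product_utility",
    "share_of_preference",
    "run_scenarios",
    "DEFAULT_PRODUCTS",
    "DEFAULT_SCENARIOS",
]


@dataclass(frozen=True)
class ProductProfile:
    """A (hypothetical) contrast agent: one numeric value per attribute."""

    name: str
    values: dict

    def validate(self, space: list[AttributeSpec]) -> None:
        idx = attribute_index(list(space))
        missing = set(idx) - set(self.values)
        if missing:
            raise ValueError(f"product {self.name!r} missing attributes {sorted(missing)}")
        for name, spec in idx.items():
            v = float(self.values[name])
            if not math.isfinite(v):
                raise ValueError(f"product {self.name!r}: non-finite value for {name!r}")
            if spec.scale == "log" and v <= 0:
                raise ValueError(
                    f"product {self.name!r}: {name!r} is log-scaled, needs value > 0"
                )


# The six simulation products: three marketed agents (A-C, published
# property values) and three hypothetical ones (D-F).
DEFAULT_PRODUCTS: dict[str, ProductProfile] = {
    p.name: p
    for p in [
        ProductProfile("Existing product A", {
            "sensitivity": 83, "cost": 83, "retention": 4.5,
            "severe_reaction": 2.1, "mild_reaction": 39}),
        ProductProfile("Existing product B", {
            "sensitivity": 94, "cost": 100, "retention": 4.0,
            "severe_reaction": 12, "mild_reaction": 130}),
        ProductProfile("Existing product C", {
            "sensitivity": 94, "cost": 72, "retention": 0.2,
            "severe_reaction": 5.7, "mild_reaction": 150}),
        ProductProfile("Test product D", {
            "sensitivity": 83, "cost": 25, "retention": 20,
            "severe_reaction": 1.6, "mild_reaction": 12}),
        ProductProfile("Test product E", {
            "sensitivity": 78, "cost": 100, "retention": 0.2,
            "severe_reaction": 12, "mild_reaction": 72}),
        ProductProfile("Test product F", {
            "sensitivity": 83, "cost": 75, "retention": 0.1,
            "severe_reaction": 18, "mild_reaction": 130}),
    ]
}

DEFAULT_SCENARIOS: dict[str, list[str]] = {
    "Scenario 1": ["Existing product A", "Existing product B", "Existing product C"],
    "Scenario 2": ["Test product D", "Existing product A", "Existing product B",
                   "Existing product C"],
    "Scenario 3": ["Test product E", "Existing product A", "Existing product B",
                   "Existing product C"],
    "Scenario 4": ["Test product F", "Existing product A", "Existing product B",
                   "Existing product C"],
    "Scenario 5": ["Existing product A", "Existing product B", "Existing product C",
                   "Test product D", "Test product E", "Test product F"],
}


@dataclass
class ShareResult:
    """Preference shares for one scenario.

    ``overall`` maps product name -> share (%); ``per_respondent`` is
    (n_respondents, n_products) in percent, rows summing to 100.
    """

    scenario: str
    products: list[str]
    overall: dict[str, float]
    per_respondent: np.ndarray
    respondent_ids: list
    method: str
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "product": self.products,
                "share_pct": [self.overall[p] for p in self.products],
                "method": self.method,
            }
        )


def utility_at_value(
    spec: AttributeSpec, level_utilities: np.ndarray, value: float
) -> float | np.ndarray:
    """Utility of an arbitrary attribute value by interpolation.

    Piecewise-linear between adjacent level utilities on the attribute's
    axis (raw values for linear scale, log10 for log scale); values outside
    the level range are linearly extrapolated from the two boundary levels.
    ``level_utilities`` may be (L,) or (n, L) for many respondents at once.
    """
    u = np.asarray(level_utilities, dtype=float)
    if u.shape[-1] != spec.n_levels:
        raise ValueError(
            f"{spec.name!r}: expected {spec.n_levels} level utilities, got {u.shape[-1]}"
        )
    if spec.scale == "log":
        if value <= 0:
            raise ValueError(f"{spec.name!r} is log-scaled; value must be > 0")
        x = math.log10(value)
    else:
        x = float(value)
    axis = np.asarray(spec.axis())

    j = int(np.searchsorted(axis, x))
    if j <= 0:
        lo, hi = 0, 1
    elif j >= len(axis):
        lo, hi = len(axis) - 2, len(axis) - 1
    else:
        lo, hi = j - 1, j
    w = (x - axis[lo]) / (axis[hi] - axis[lo])
    return u[..., lo] * (1.0 - w) + u[..., hi] * w


def product_utility(
    partworths: PartWorthSet, product: ProductProfile, space: list[AttributeSpec]
) -> np.ndarray:
    """Total utility of a product for every respondent (sum over attributes)."""
    product.validate(space)
    total = np.zeros(partworths.n_respondents)
    for spec in space:
        total += np.asarray(
            utility_at_value(spec, partworths.utilities[spec.name], product.values[spec.name])
        )
    return total


def _utility_matrix(
    partworths: PartWorthSet,
    products: list[ProductProfile],
    space: list[AttributeSpec],
) -> np.ndarray:
    return np.column_stack(
        [product_utility(partworths, p, space) for p in products]
    )


def share_of_preference(
    partworths: PartWorthSet,
    products: list[ProductProfile],
    space: list[AttributeSpec],
    method: str = "logit",
    rfc_noise: float = 1.0,
    n_draws: int = 10_000,
    seed: int | None = None,
    scenario: str = "scenario",
) -> ShareResult:
    """Preference shares for a competitive set of products.

    ``logit`` is the share-of-preference rule (exponentiated total utility,
    rescaled to 100% per respondent, averaged); ``first_choice`` assigns
    each respondent to their argmax product; ``rfc`` tallies first choices
    under Gumbel-perturbed utilities over ``n_draws`` Monte-Carlo draws.
    """
    if len(products) < 2:
        raise ValueError("need at least 2 products")
    names = [p.name for p in products]
    if len(set(names)) != len(names):
        raise ValueError("duplicate product names")
    if partworths.n_respondents == 0:
        raise ValueError("empty respondent set")

    U = _utility_matrix(partworths, products, space)  # (n, P)

    if method == "logit":
        shifted = U - U.max(axis=1, keepdims=True)
        expu = np.exp(shifted)
        shares = expu / expu.sum(axis=1, keepdims=True) * 100.0
        used_seed = None
    elif method == "first_choice":
        best = U.argmax(axis=1)
        shares = np.zeros_like(U)
        shares[np.arange(len(U)), best] = 100.0
        used_seed = None
    elif method == "rfc":
        if rfc_noise <= 0:
            raise ValueError("rfc requires rfc_noise > 0")
        if seed is None:
            raise ValueError("rfc requires a seed")
        rng = np.random.default_rng(seed)
        counts = np.zeros_like(U)
        chunk = max(1, min(n_draws, int(2e7 / U.size)))
        done = 0
        while done < n_draws:
            k = min(chunk, n_draws - done)
            noise = rng.gumbel(scale=rfc_noise, size=(k,) + U.shape)
            best = (U[None, :, :] + noise).argmax(axis=2)  # (k, n)
            for pi in range(U.shape[1]):
                counts[:, pi] += (best == pi).sum(axis=0)
            done += k
        shares = counts / n_draws * 100.0
        used_seed = seed
    else:
        raise ValueError(f"unknown method {method!r}")

    overall = {name: float(shares[:, i].mean()) for i, name in enumerate(names)}
    return ShareResult(
        scenario=scenario,
        products=names,
        overall=overall,
        per_respondent=shares,
        respondent_ids=list(partworths.respondent_ids),
        method=method,
        seed=used_seed,
    )


def run_scenarios(
    partworths: PartWorthSet,
    space: list[AttributeSpec],
    scenarios: dict[str, list[str]] | None = None,
    products: dict[str, ProductProfile] | None = None,
    method: str = "logit",
    rfc_noise: float = 1.0,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> list[ShareResult]:
    """Compute shares for each named scenario (defaults: the six standard
    products and the five standard competitive scenarios)."""
    scenarios = scenarios if scenarios is not None else DEFAULT_SCENARIOS
    products = products if products is not None else DEFAULT_PRODUCTS
    results = []
    for name, product_names in scenarios.items():
        unknown = [p for p in product_names if p not in products]
        if unknown:
            raise KeyError(f"scenario {name!r} references unknown products {unknown}")
        profile_list = [products[p] for p in product_names]
        results.append(
            share_of_preference(
                partworths,
                profile_list,
                space,
                method=method,
                rfc_noise=rfc_noise,
                n_draws=n_draws,
                seed=seed,
                scenario=name,
            )
        )
    return results
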