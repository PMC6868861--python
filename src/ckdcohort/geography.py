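"""Urban/rural residence classification via RUCA codes.

Patient zip codes map through a zip -> RUCA crosswalk, and RUCA codes
partition into urban vs rural by a "category C"-style binary
categorization (urban-focused secondary codes 1.0, 1.1, 2.0, 2.1, 3.0,
4.1, 5.1, 7.1, 8.1 and 10.1 are urban; the remaining secondary codes are
rural). The partition ships as an editable data file — it is
configuration, not hard-coded truth. Patients with no zip code, an
unmapped zip, or a malformed zip are ``unclassified``, each with a
distinct logged reason, so urban + rural + unclassified always equals
the cohort size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

URBAN = "urban"
RURAL = "rural"
UNCLASSIFIED = "unclassified"

_ZIP5 = re.compile(r"^\d{5}$")


def load_default_categories() -> dict[float, str]:
    """The bundled RUCA-code -> urban/rural partition."""
    with resources.files("ckdcohort.data").joinpath("ruca_categories.csv").open() as fh:
        df = pd.read_csv(fh)
    return {float(r.ruca_code): str(r.category) for r in df.itertuples()}


@dataclass
class RucaCrosswalk:
    """zip (5-char string) -> RUCA code, plus the urban/rural partition of
    RUCA codes. Every code in the categorization belongs to exactly one
    of urban/rural."""

    zip_to_ruca: dict[str, float]
    categories: dict[float, str] | None = None

    def __post_init__(self) -> None:
        if self.categories is None:
            self.categories = load_default_categories()
        bad = {c for c in self.categories.values()} - {URBAN, RURAL}
        if bad:
            raise ValueError(f"RUCA categorization must be urban/rural only, got {bad}")

    @classmethod
    def from_files(
        cls, crosswalk_path: str | Path, categories_path: str | Path | None = None
    ) -> "RucaCrosswalk":
        xw = pd.read_csv(crosswalk_path, dtype={"zip": str, "ruca_code": float})
        mapping = {str(r.zip).zfill(5): float(r.ruca_code) for r in xw.itertuples()}
        categories = None
        if categories_path is not None:
            cat = pd.read_csv(categories_path)
            categories = {float(r.ruca_code): str(r.category) for r in cat.itertuples()}
        return cls(zip_to_ruca=mapping, categories=categories)


def normalize_zip(zip_code: str | None) -> str | None:
    """Strip to the 5-digit zip (ZIP+4 truncates); ``None`` if malformed."""
    if zip_code is None:
        return None
    z = zip_code.strip().split("-")[0]
    if len(z) > 5:
        z = z[:5]
    return z if _ZIP5.match(z) else None


def classify_residence(
    zip_code: str | None, crosswalk: RucaCrosswalk
) -> tuple[str, str | None]:
    """Classify one residence as urban/rural/unclassified.

    Returns ``(category, reason)`` where reason is ``None`` for a
    classified zip and one of ``missing`` / ``malformed`` / ``unmapped``
    otherwise. Depends only on the zip and the crosswalk.
    """
    if zip_code is None or not zip_code.strip():
        return UNCLASSIFIED, "missing"
    z = normalize_zip(zip_code)
    if z is None:
        return UNCLASSIFIED, "malformed"
    ruca = crosswalk.zip_to_ruca.get(z)
    if ruca is None:
        return UNCLASSIFIED, "unmapped"
    category = crosswalk.categories.get(ruca)
    if category is None:
        return UNCLASSIFIED, "uncategorized_ruca"
    return category, None


def classify_cohort(
    zips: dict[str, str | None], crosswalk: RucaCrosswalk
) -> dict[str, tuple[str, str | None]]:
    """Classify every patient; the result is a partition of the cohort."""
    return {pid: classify_residence(z, crosswalk) for pid, z in zips.items()}
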