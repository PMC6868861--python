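"""STROBE-style attrition accounting.

Counts flow from candidate records through the permissive repository
tier to the strict registry tier, with per-condition subtotals (not
mutually exclusive — their sum may exceed the registry count), the
PCOS-exclusion tally, and the urban/rural/unclassified residence
partition. Serialization is bit-stable: keys sorted, no timestamps (run
timing lives in the manifest).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .config import CriteriaConfig
from .geography import RURAL, UNCLASSIFIED, URBAN
from .model import ConditionFlags


@dataclass
class AttritionReport:
    n_candidates: int
    n_repository: int
    n_registry: int
    n_ckd: int
    n_htn: int
    n_dm: int
    n_prediabetes: int
    n_pcos_excluded: int
    n_urban: int
    n_rural: int
    n_unclassified: int
    config_hash: str

    def __post_init__(self) -> None:
        assert self.n_registry <= self.n_repository <= self.n_candidates
        assert self.n_urban + self.n_rural + self.n_unclassified == self.n_candidates
        for n in (self.n_ckd, self.n_htn, self.n_dm, self.n_prediabetes):
            assert n <= self.n_registry

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [
            "Participant flow",
            f"  candidate records ............ {self.n_candidates}",
            f"  repository (any single measure) {self.n_repository}",
            f"  registry (guideline criteria) . {self.n_registry}",
            "  condition subtotals (not mutually exclusive):",
            f"    CKD ........................ {self.n_ckd}",
            f"    hypertension ............... {self.n_htn}",
            f"    diabetes ................... {self.n_dm}",
            f"    prediabetes ................ {self.n_prediabetes}",
            f"  DM cleared by PCOS-metformin exclusion: {self.n_pcos_excluded}",
            "  residence:",
            f"    urban ...................... {self.n_urban}",
            f"    rural ...................... {self.n_rural}",
            f"    unclassified ............... {self.n_unclassified}",
            f"  config hash: {self.config_hash[:12]}",
        ]
        return "\n".join(lines) + "\n"


def strobe_report(
    flags: dict[str, ConditionFlags],
    geo: dict[str, tuple[str, str | None]],
    config: CriteriaConfig,
) -> AttritionReport:
    """Aggregate per-patient flags and residence classes into the flow
    report. ``geo`` must cover every patient in ``flags``."""
    counts = {URBAN: 0, RURAL: 0, UNCLASSIFIED: 0}
    for pid in flags:
        category = geo.get(pid, (UNCLASSIFIED, "missing"))[0]
        counts[category] += 1
    return AttritionReport(
        n_candidates=len(flags),
        n_repository=sum(f.in_repository for f in flags.values()),
        n_registry=sum(f.in_registry for f in flags.values()),
        n_ckd=sum(f.ckd for f in flags.values()),
        n_htn=sum(f.htn for f in flags.values()),
        n_dm=sum(f.dm for f in flags.values()),
        n_prediabetes=sum(f.prediabetes for f in flags.values()),
        n_pcos_excluded=sum(f.pcos_excluded_dm for f in flags.values()),
        n_urban=counts[URBAN],
        n_rural=counts[RURAL],
        n_unclassified=counts[UNCLASSIFIED],
        config_hash=config.config_hash(),
    )
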