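"""Conservative per-substance hit calls for genotoxicity assays.

Assay records from heterogeneous sources are aggregated to one call per
substance and test type under the conservative rule used in regulatory
genotoxicity assessment: a substance is *negative* only if every result for
that test is negative; one or more positive results make it *positive*,
regardless of how many negatives accompany them.

Six test types are recognised — Ames (bacterial reverse mutation), in vitro
mammalian cell gene mutation (MCGM), in vitro and in vivo micronucleus (MN),
in vitro and in vivo chromosomal aberration (CA) — plus the pooled
"all genotoxicity" endpoint, whose call applies the same rule over every
result of every type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

TEST_TYPES: tuple[str, ...] = (
    "ames",
    "invitro_mcgm",
    "invitro_mn",
    "invitro_ca",
    "invivo_mn",
    "invivo_ca",
)

ALL_GENOTOX = "all"

POSITIVE = "positive"
NEGATIVE = "negative"

#: Source-vocabulary aliases → canonical test type.  Extend via the
#: ``aliases`` argument of :func:`load_assay_results`.
DEFAULT_TEST_ALIASES: dict[str, str] = {
    "ames": "ames",
    "bacterial reverse mutation": "ames",
    "in vitro mcgm": "invitro_mcgm",
    "invitro_mcgm": "invitro_mcgm",
    "in vitro mn": "invitro_mn",
    "invitro_mn": "invitro_mn",
    "in vitro ca": "invitro_ca",
    "invitro_ca": "invitro_ca",
    "in vivo mn": "invivo_mn",
    "invivo_mn": "invivo_mn",
    "in vivo ca": "invivo_ca",
    "invivo_ca": "invivo_ca",
}

_CALL_ALIASES = {
    "positive": POSITIVE,
    "pos": POSITIVE,
    "+": POSITIVE,
    "negative": NEGATIVE,
    "neg": NEGATIVE,
    "-": NEGATIVE,
}


@dataclass(frozen=True)
class AssayResult:
    inchi: str
    test_type: str
    call: str
    source_dataset: str

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"unknown test_type {self.test_type!r}")
        if self.call not in (POSITIVE, NEGATIVE):
            raise ValueError(f"call must be positive/negative, got {self.call!r}")


@dataclass
class EndpointSet:
    """Deduplicated substance set for one test type with aggregated calls."""

    test_type: str
    members: set[str] = field(default_factory=set)
    aggregated_call: dict[str, str] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.aggregated_call.values() if c == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for c in self.aggregated_call.values() if c == NEGATIVE)


def aggregate_calls(calls: Iterable[str]) -> str:
    """One conservative call from ≥1 results: any positive ⇒ positive."""
    calls = list(calls)
    if not calls:
        raise ValueError("cannot aggregate an empty result list (no-call)")
    return POSITIVE if POSITIVE in calls else NEGATIVE


def load_assay_results(
    df: pd.DataFrame, aliases: dict[str, str] | None = None
) -> tuple[list[AssayResult], int]:
    """Parse an assay table [inchi, test_type, call, dataset].

    Test-type labels are mapped through the alias table (case-insensitive);
    an unknown label is a hard error carrying row provenance.  Equivocal or
    otherwise non-binary calls are dropped with a logged count — only
    positive/negative results enter the aggregation.
    Returns (results, n_dropped_equivocal).
    """
    alias_map = {k.lower(): v for k, v in DEFAULT_TEST_ALIASES.items()}
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    results: list[AssayResult] = []
    dropped = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        label = str(row.test_type).strip().lower()
        if label not in alias_map:
            raise ValueError(f"row {idx}: unknown test_type {row.test_type!r}")
        call = _CALL_ALIASES.get(str(row.call).strip().lower())
        if call is None:
            dropped += 1
            continue
        results.append(
            AssayResult(
                inchi=row.inchi,
                test_type=alias_map[label],
                call=call,
                source_dataset=str(getattr(row, "dataset", "")),
            )
        )
    if dropped:
        logger.info("dropped %d equivocal/non-binary assay results", dropped)
    return results, dropped


def build_endpoint_sets(results: Iterable[AssayResult]) -> dict[str, EndpointSet]:
    """Six per-test endpoint sets plus the pooled all-genotoxicity set.

    Membership in a test's set requires ≥1 result of that type; the pooled
    set aggregates over the full result list of every type (equivalent, under
    the any-positive rule, to a positive-dominant vote over per-test calls).
    """
    per_test: dict[str, dict[str, list[str]]] = {t: {} for t in TEST_TYPES}
    pooled: dict[str, list[str]] = {}
    for r in results:
        per_test[r.test_type].setdefault(r.inchi, []).append(r.call)
        pooled.setdefault(r.inchi, []).append(r.call)

    endpoint_sets: dict[str, EndpointSet] = {}
    for test, by_substance in per_test.items():
        endpoint_sets[test] = EndpointSet(
            test_type=test,
            members=set(by_substance),
            aggregated_call={i: aggregate_calls(c) for i, c in by_substance.items()},
        )
    endpoint_sets[ALL_GENOTOX] = EndpointSet(
        test_type=ALL_GENOTOX,
        members=set(pooled),
        aggregated_call={i: aggregate_calls(c) for i, c in pooled.items()},
    )
    return endpoint_sets
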