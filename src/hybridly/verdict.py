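"""Integration of the evidence lines into a machine-readable parentage verdict.

The decision logic formalizes the qualitative reasoning of a hybrid-origin
diagnosis:

* heterozygosity fold-elevation over every candidate => F1 hybrid;
* a candidate is supported as a parent when its allele-sharing CI covers
  0.5 AND it is corroborated either as the maternal (organellar) parent or
  as the donor of the hybrid's non-reference alleles (g >= g_min) — with a
  reference assembly derived from one candidate, the sharing fraction alone
  cannot separate candidates, so corroboration is required;
* a candidate not supported whose alt-sharing g falls below g_min is
  excluded as the second parent;
* when no candidate qualifies as the second parent the verdict notes that
  the second parent is not among the sampled candidates.

All thresholds live in :class:`VerdictParams`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .allele_sharing import AllelePartition, SharingTest, sharing_fractions
from .its_alleles import ITSAlleleTable
from .organelle_distance import MaternalAssignment
from .snp_stats import DensityReport

SCHEMA_VERSION = 1

__all__ = ["VerdictParams", "HybridVerdict", "decide", "render_report", "verdict_from_json"]


@dataclass(frozen=True)
class VerdictParams:
    fold_min: float = 10.0  # minimal hybrid/candidate intra-SNP fold
    g_min: float = 0.2  # minimal alt-sharing to remain a second-parent candidate
    tie_ratio: float = 1.1  # maternal margin below which assignment is ambiguous
    ci_level: float = 0.95
    its_min_support: int = 3

    def __post_init__(self) -> None:
        if self.fold_min <= 1:
            raise ValueError("fold_min must exceed 1")
        if not 0 < self.g_min < 1:
            raise ValueError("g_min must be in (0, 1)")


@dataclass
class HybridVerdict:
    schema_version: int
    hybrid: str
    candidates: list[str]
    is_hybrid: bool
    folds: dict[str, float | None]  # candidate -> fold (None: candidate total 0)
    maternal: str | None
    maternal_margin: float
    supported_parents: list[dict]  # candidate, f, ci, p
    excluded_candidates: list[dict]  # candidate, g
    its_consistent: bool | None
    narrative: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        def default(obj):
            raise TypeError(f"not JSON-serializable: {obj!r}")

        data = self.to_dict()
        # inf margins survive a round-trip as strings
        if data["maternal_margin"] == float("inf"):
            data["maternal_margin"] = "inf"
        return json.dumps(data, indent=1, default=default)


def _fold_ok(fold: float | None, hybrid_total: int, fold_min: float) -> bool:
    if fold is None:  # candidate total is zero
        return hybrid_total > 0
    return fold >= fold_min


def decide(
    density: DensityReport,
    sharing_tests: dict[str, SharingTest],
    partition: AllelePartition,
    maternal_result: MaternalAssignment,
    its_table: ITSAlleleTable | None = None,
    params: VerdictParams = VerdictParams(),
) -> HybridVerdict:
    """Combine densities, sharing, organellar and ITS evidence into a verdict."""
    hybrid = partition.hybrid
    candidates = list(partition.candidates)

    mismatches = []
    if density.hybrid != hybrid:
        mismatches.append(f"density report hybrid {density.hybrid!r} != {hybrid!r}")
    for c in candidates:
        if c not in density.total_count:
            mismatches.append(f"candidate {c!r} missing from density report")
        if c not in maternal_result.distances:
            mismatches.append(f"candidate {c!r} missing from maternal distances")
    for c in sharing_tests:
        if c not in candidates:
            mismatches.append(f"sharing test for non-candidate {c!r}")
    if mismatches:
        raise ValueError("inconsistent sample names across inputs: " + "; ".join(mismatches))

    hybrid_total = density.total_count[hybrid]
    folds = {c: density.fold_vs[c] for c in candidates}
    is_hybrid = all(_fold_ok(folds[c], hybrid_total, params.fold_min) for c in candidates)

    supported: list[dict] = []
    excluded: list[dict] = []
    g: dict[str, float | None] = {c: None for c in candidates}
    if is_hybrid and partition.informative_sites > 0:
        _f, g = sharing_fractions(partition)
        maternal = maternal_result.maternal
        for c in candidates:
            test = sharing_tests.get(c)
            ci_ok = test is not None and test.ci_covers(0.5)
            g_c = g[c]
            second_parent_like = g_c is not None and g_c >= params.g_min
            if ci_ok and (second_parent_like or c == maternal):
                supported.append(
                    {
                        "candidate": c,
                        "f": test.point_estimate,
                        "ci": [test.ci_low, test.ci_high],
                        "p_vs_half": test.p_value,
                    }
                )
            elif g_c is not None and g_c < params.g_min:
                excluded.append({"candidate": c, "g": g_c})

    verdict = HybridVerdict(
        schema_version=SCHEMA_VERSION,
        hybrid=hybrid,
        candidates=candidates,
        is_hybrid=is_hybrid,
        folds=folds,
        maternal=maternal_result.maternal,
        maternal_margin=maternal_result.margin,
        supported_parents=supported,
        excluded_candidates=excluded,
        its_consistent=None,
        narrative="",
    )
    if its_table is not None:
        verdict.its_consistent = _its_consistent(verdict, its_table, params)
    verdict.narrative = _narrative(verdict, g, params)
    return verdict


def _shares_its_allele(
    table: ITSAlleleTable, a: str, b: str, min_support: int
) -> bool:
    return any(
        allele.support.get(a, 0) >= min_support
        and allele.support.get(b, 0) >= min_support
        for allele in table.alleles
    )


def _its_consistent(
    verdict: HybridVerdict, table: ITSAlleleTable, params: VerdictParams
) -> bool:
    hybrid = verdict.hybrid
    ok = all(
        _shares_its_allele(table, hybrid, entry["candidate"], params.its_min_support)
        for entry in verdict.supported_parents
    )
    ok = ok and all(
        not _shares_its_allele(table, hybrid, entry["candidate"], params.its_min_support)
        for entry in verdict.excluded_candidates
    )
    return ok


def _narrative(
    verdict: HybridVerdict, g: dict[str, float | None], params: VerdictParams
) -> str:
    lines: list[str] = []
    fold_bits = ", ".join(
        f"{c}: {'undefined (zero SNPs)' if f is None else format(f, '.1f') + 'x'}"
        for c, f in verdict.folds.items()
    )
    if not verdict.is_hybrid:
        lines.append(
            f"Sample {verdict.hybrid!r} shows no intragenomic SNP elevation over the "
            f"candidates (folds: {fold_bits}; threshold {params.fold_min}x): "
            "no evidence of hybrid origin."
        )
        return " ".join(lines)
    lines.append(
        f"Sample {verdict.hybrid!r} shows strong intragenomic SNP elevation "
        f"(folds: {fold_bits}; threshold {params.fold_min}x): consistent with an "
        "F1 hybrid."
    )
    if verdict.maternal is not None:
        lines.append(
            f"Organellar distances assign {verdict.maternal!r} as the maternal "
            f"(female) parent (margin {verdict.maternal_margin:.2f})."
        )
    else:
        lines.append("Organellar distances leave the maternal parent ambiguous.")
    for entry in verdict.supported_parents:
        lines.append(
            f"Candidate {entry['candidate']!r} is supported as a parent: sharing "
            f"fraction {entry['f']:.3f} (95% CI {entry['ci'][0]:.3f}-{entry['ci'][1]:.3f}) "
            "is compatible with the F1 expectation of one allele per site."
        )
    for entry in verdict.excluded_candidates:
        lines.append(
            f"Candidate {entry['candidate']!r} is excluded as the second parent: "
            f"only {entry['g']:.3f} of the hybrid's non-reference alleles are found "
            f"in its genotype (threshold {params.g_min})."
        )
    second_parent_found = any(
        g.get(entry["candidate"]) is not None
        and g[entry["candidate"]] >= params.g_min
        for entry in verdict.supported_parents
    )
    if not second_parent_found:
        lines.append(
            "The second parent is not among the sampled candidates; its identity "
            "cannot be computed from this data set."
        )
    if verdict.its_consistent is True:
        lines.append("The ITS allele table is consistent with this parentage.")
    elif verdict.its_consistent is False:
        lines.append("Warning: the ITS allele table conflicts with this parentage.")
    return " ".join(lines)


def render_report(verdict: HybridVerdict, path: str | Path | None = None) -> tuple[str, str]:
    """Serialize the verdict as (JSON, human-readable text); optionally write.

    When ``path`` is given the JSON goes to ``path`` and the text next to it
    with a ``.txt`` suffix.
    """
    payload = verdict.to_json()
    text = verdict.narrative
    if path is not None:
        path = Path(path)
        path.write_text(payload + "\n")
        path.with_suffix(".txt").write_text(text + "\n")
    return payload, text


def verdict_from_json(payload: str) -> HybridVerdict:
    data = json.loads(payload)
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {data.get('schema_version')}")
    if data["maternal_margin"] == "inf":
        data["maternal_margin"] = float("inf")
    return HybridVerdict(**data)
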