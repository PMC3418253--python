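"""The five-stage screening cascade: orchestration, scoring, ranking, reports.

Stage order (fixed): signal peptide -> annotation (poorly annotated focus)
-> convertase motif downstream of the signal -> transmembrane rule ->
glycosylation -> cross-species homology.  Records are eliminated at the
first failing stage; survivors receive a combined score (weighted mean of
five normalised stage scores — signal score, convertase cleavage-site
density, TM penalty, glycosylation fraction, minimum pairwise identity) and
are ranked descending, ties broken by record id.

Ortholog pairing across species files uses the ``<base>_<species>`` id
suffix convention: the base id is the record id with a trailing
``_<species label>`` stripped when the label matches a corpus species.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import yaml

from pepscreen.convertase import DEFAULT_MOTIFS, scan_convertase_motifs
from pepscreen.glyco import is_heavily_glycosylated
from pepscreen.homology import HomologyReport, meets_homology_threshold, pairwise_report
from pepscreen.mass import DEFAULT_MASS_WINDOW, excise_candidates
from pepscreen.membrane import detect_tm_segments
from pepscreen.records import ProteinRecord
from pepscreen.signal_peptide import predict_signal_peptide

STAGES = ("signal_peptide", "annotation", "convertase", "tm",
          "glycosylation", "homology")

DEFAULT_KEYWORDS = ("hypothetical", "uncharacterized", "Rik",
                    "open reading frame")


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the cascade; round-trips losslessly through YAML.

    ``tm_rule_reading`` selects how a lone TM domain is handled:
    ``"single"`` (default) eliminates single-TM proteins lacking a
    convertase motif; ``"signal"`` eliminates proteins whose predicted
    signal region doubles as a TM anchor and that lack a motif.  In both
    readings proteins with two or more TM domains are eliminated.
    ``glyco_scope`` applies the heavy-glycosylation rule to the excised
    peptide regions (``"peptide"``, default) or the whole protein
    (``"protein"``).
    """

    signal_threshold: float = 0.45
    das_cutoff: float = 2.0
    glyco_potential_threshold: float = 0.6
    glyco_max_sites: int = 2
    homology_threshold_percent: float = 50.0
    motif_set: tuple[str, ...] = DEFAULT_MOTIFS
    mass_window_da: tuple[float, float] = DEFAULT_MASS_WINDOW
    uncharacterized_keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    tm_rule_reading: str = "single"
    glyco_scope: str = "peptide"
    homology_denominator: str = "columns"
    required_species: tuple[str, ...] = ()
    score_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_threshold <= 1.0):
            raise ValueError("signal_threshold must be in [0, 1]")
        if self.glyco_max_sites < 0:
            raise ValueError("glyco_max_sites must be non-negative")
        if not (0.0 <= self.homology_threshold_percent <= 100.0):
            raise ValueError("homology_threshold_percent must be in [0, 100]")
        if self.tm_rule_reading not in ("single", "signal"):
            raise ValueError("tm_rule_reading must be 'single' or 'signal'")
        if self.glyco_scope not in ("peptide", "protein"):
            raise ValueError("glyco_scope must be 'peptide' or 'protein'")
        if self.mass_window_da[0] > self.mass_window_da[1]:
            raise ValueError("mass_window_da must be (low, high)")
        if len(self.score_weights) != 5:
            raise ValueError("score_weights must have 5 entries")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("motif_set", "mass_window_da", "uncharacterized_keywords",
                    "required_species", "score_weights"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScreenConfig":
        kwargs = dict(d)
        for key in ("motif_set", "mass_window_da", "uncharacterized_keywords",
                    "required_species", "score_weights"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass(frozen=True)
class RecordResult:
    """Per-record outcome: stage evidence, elimination or score and rank."""

    id: str
    species: str
    base_id: str
    description: str
    stages_passed: tuple[str, ...]
    elimination_stage: str | None
    stage_scores: tuple[float, float, float, float, float]
    combined_score: float | None
    rank: int | None
    evidence: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages_passed"] = list(d["stages_passed"])
        d["stage_scores"] = list(d["stage_scores"])
        return d


@dataclass(frozen=True)
class ScreenResult:
    """Corpus-level screen outcome."""

    records: tuple[RecordResult, ...]
    stage_counts: tuple[tuple[str, int], ...]
    config: dict[str, Any]
    version: str

    @property
    def survivors(self) -> tuple[RecordResult, ...]:
        return tuple(r for r in self.records if r.elimination_stage is None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "records": [r.to_dict() for r in self.records],
            "stage_counts": [[name, count] for name, count in self.stage_counts],
            "config": self.config,
            "version": self.version,
        }


def combined_score(stage_scores: Sequence[float],
                   weights: Sequence[float] | None = None) -> float:
    """Weighted mean of normalised stage scores; default equal weights."""
    if weights is None:
        weights = [1.0] * len(stage_scores)
    if len(weights) != len(stage_scores):
        raise ValueError("weights length must match stage_scores")
    total = sum(weights)
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    return sum(s * w for s, w in zip(stage_scores, weights)) / total


def base_id(record_id: str, species_labels: Iterable[str]) -> str:
    """Strip a trailing ``_<species>`` suffix when it names a corpus species."""
    for sp in species_labels:
        if sp and record_id.endswith(f"_{sp}"):
            return record_id[:-(len(sp) + 1)]
    return record_id


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def _evaluate_record(rec: ProteinRecord, config: ScreenConfig,
                     orthologs: Mapping[str, ProteinRecord]) -> tuple[
                         list[str], str | None, list[float], dict[str, Any]]:
    """Run the cascade on one record; stops at the first failing stage."""
    passed: list[str] = []
    scores = [0.0, 0.0, 0.0, 0.0, 0.0]
    evidence: dict[str, Any] = {}

    # stage 1: signal peptide
    call = predict_signal_peptide(rec, config.signal_threshold)
    scores[0] = _clip01(call.score)
    evidence["signal"] = {
        "present": call.present, "score": round(call.score, 4),
        "cleavage_after": call.cleavage_after,
        "h_score": round(call.h_score, 4), "n_score": call.n_score,
        "c_score": call.c_score,
    }
    if not call.present:
        return passed, "signal_peptide", scores, evidence
    passed.append("signal_peptide")

    # stage 2: poorly annotated focus
    desc = rec.description.lower()
    keyword = next((k for k in config.uncharacterized_keywords
                    if k.lower() in desc), None)
    evidence["annotation_keyword"] = keyword
    if keyword is None:
        return passed, "annotation", scores, evidence
    passed.append("annotation")

    # stage 3: convertase motif downstream of the signal peptide
    hits = scan_convertase_motifs(rec.sequence, config.motif_set)
    boundary = call.cleavage_after or 0
    downstream = [h for h in hits if h.match_start > boundary]
    cleavage_points = sorted({h.cleavage_after for h in downstream})
    scores[1] = _clip01(len(cleavage_points) / 4.0)
    evidence["convertase"] = {
        "n_hits_downstream": len(downstream),
        "cleavage_points": cleavage_points,
    }
    if not downstream:
        return passed, "convertase", scores, evidence
    passed.append("convertase")

    # stage 4: transmembrane rule
    segments = detect_tm_segments(rec.sequence, config.das_cutoff)
    after_signal = [s for s in segments if s.start > boundary]
    n_tm = len(after_signal)
    scores[2] = _clip01(1.0 - n_tm / 2.0)
    evidence["tm"] = {
        "count": n_tm,
        "segments": [[s.start, s.end, round(s.peak_score, 3)]
                     for s in after_signal],
    }
    eliminate_tm = n_tm >= 2
    if not eliminate_tm and config.tm_rule_reading == "single":
        eliminate_tm = n_tm == 1 and not downstream
    if not eliminate_tm and config.tm_rule_reading == "signal":
        signal_anchor = any(s.start <= boundary for s in segments)
        eliminate_tm = signal_anchor and not downstream
    if eliminate_tm:
        return passed, "tm", scores, evidence
    passed.append("tm")

    # stage 5: glycosylation
    candidates = excise_candidates(rec, call, hits, config.mass_window_da)
    if config.glyco_scope == "protein":
        heavy_flags = [is_heavily_glycosylated(
            rec.sequence, config.glyco_potential_threshold,
            config.glyco_max_sites)]
        candidate_heavy = [None] * len(candidates)
    else:
        candidate_heavy = [is_heavily_glycosylated(
            c.sequence, config.glyco_potential_threshold,
            config.glyco_max_sites) for c in candidates]
        heavy_flags = candidate_heavy
    heavy_fraction = (sum(heavy_flags) / len(heavy_flags)) if heavy_flags else 0.0
    scores[3] = _clip01(1.0 - heavy_fraction)
    evidence["candidates"] = [
        {"start": c.start, "end": c.end, "length": len(c.sequence),
         "n_flank": c.n_flank, "c_flank": c.c_flank,
         "average_mass_da": round(c.average_mass_da, 4),
         "monoisotopic_mass_da": round(c.monoisotopic_mass_da, 4),
         "heavily_glycosylated": h}
        for c, h in zip(candidates, candidate_heavy)
    ]
    evidence["heavy_glyco_fraction"] = round(heavy_fraction, 4)
    if heavy_flags and all(heavy_flags):
        return passed, "glycosylation", scores, evidence
    passed.append("glycosylation")

    # stage 6: cross-species homology
    if not orthologs:
        scores[4] = 1.0  # single-species corpus: gate not applicable
        evidence["homology"] = {"pairwise_identity_pct": {}, "note":
                                "single species; homology gate skipped"}
        passed.append("homology")
        return passed, None, scores, evidence
    reports: list[HomologyReport] = []
    missing = []
    for sp, ortho in orthologs.items():
        if ortho is None:
            missing.append(sp)
            continue
        reports.append(pairwise_report(
            rec.id, rec.sequence, ortho.id, ortho.sequence,
            species_a=rec.species, species_b=sp,
            denominator=config.homology_denominator))
    identities = {r.id_b: round(r.percent_identity, 2) for r in reports}
    min_identity = min((r.percent_identity for r in reports), default=0.0)
    if missing:
        min_identity = 0.0
    scores[4] = _clip01(min_identity / 100.0)
    evidence["homology"] = {"pairwise_identity_pct": identities,
                            "missing_orthologs": missing}
    ok = (not missing and reports
          and meets_homology_threshold(reports, config.homology_threshold_percent))
    if not ok:
        return passed, "homology", scores, evidence
    passed.append("homology")
    return passed, None, scores, evidence


def run_screen(corpus: Mapping[str, Sequence[ProteinRecord]],
               config: ScreenConfig | None = None) -> ScreenResult:
    """Run the cascade over a multi-species corpus and rank survivors.

    ``corpus`` maps species label -> records.  Raises for duplicate record
    ids and for required species missing from the corpus.  An empty corpus
    yields an empty result with zero counts.
    """
    from pepscreen import __version__

    config = config or ScreenConfig()
    species = tuple(corpus.keys())
    for sp in config.required_species:
        if sp not in corpus:
            raise ValueError(f"required species {sp!r} absent from corpus")
    active_species = config.required_species or species

    seen: set[str] = set()
    index: dict[str, dict[str, ProteinRecord]] = {}  # base -> species -> rec
    for sp, records in corpus.items():
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            rec = rec if rec.species == sp else rec.with_species(sp)
            index.setdefault(base_id(rec.id, species), {})[sp] = rec

    results: list[RecordResult] = []
    for base in index:
        family = index[base]
        for sp in species:
            rec = family.get(sp)
            if rec is None:
                continue
            others = {osp: family.get(osp) for osp in active_species
                      if osp != sp}
            passed, eliminated, scores, evidence = _evaluate_record(
                rec, config, others)
            results.append(RecordResult(
                id=rec.id, species=sp, base_id=base,
                description=rec.description,
                stages_passed=tuple(passed), elimination_stage=eliminated,
                stage_scores=tuple(round(s, 6) for s in scores),
                combined_score=None, rank=None, evidence=evidence))

    results.sort(key=lambda r: r.id)
    survivors = [r for r in results if r.elimination_stage is None]
    scored = sorted(
        survivors,
        key=lambda r: (-combined_score(r.stage_scores, config.score_weights),
                       r.id))
    rank_of = {r.id: i + 1 for i, r in enumerate(scored)}
    final: list[RecordResult] = []
    for r in results:
        if r.elimination_stage is None:
            final.append(dataclasses.replace(
                r,
                combined_score=round(
                    combined_score(r.stage_scores, config.score_weights), 6),
                rank=rank_of[r.id]))
        else:
            final.append(r)

    counts = [("input", len(final))]
    for i, stage in enumerate(STAGES):
        n = sum(1 for r in final if len(r.stages_passed) > i)
        counts.append((stage, n))
    return ScreenResult(records=tuple(final), stage_counts=tuple(counts),
                        config=config.to_dict(), version=__version__)


_TSV_COLUMNS = [
    "rank", "id", "species", "base_id", "elimination_stage",
    "combined_score", "signal_score", "convertase_score", "tm_score",
    "glyco_score", "homology_score", "description",
]


def write_report(result: ScreenResult, path: str, format: str = "tsv") -> None:
    """Write the screen result: ``tsv`` (one row per record, survivors first
    by rank) or ``json`` (full evidence; reloads to ``result.to_dict()``)."""
    if format == "json":
        with open(path, "w") as handle:
            json.dump(result.to_dict(), handle, indent=1, sort_keys=False)
            handle.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    ranked = sorted(result.records,
                    key=lambda r: (r.rank is None, r.rank or 0, r.id))
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in ranked:
        s = r.stage_scores
        row = [
            "" if r.rank is None else str(r.rank),
            r.id, r.species, r.base_id,
            r.elimination_stage or "",
            "" if r.combined_score is None else f"{r.combined_score:.4f}",
            f"{s[0]:.4f}", f"{s[1]:.4f}", f"{s[2]:.4f}", f"{s[3]:.4f}",
            f"{s[4]:.4f}",
            r.description,
        ]
        lines.append("\t".join(row))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
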