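"""The automated curation filters and their orchestration.

Five cleaning steps are applied in a fixed order to a taxonomy-annotated
barcode dataset:

1. **fungal** — remove sequences that a bootstrap k-mer classifier
   confidently assigns to Fungi (cutoff 0.90 at the decision rank).
2. **non_target** — remove sequences whose best global-alignment
   identity against a trusted marker reference set is below 70%
   (off-target loci mislabelled as the marker).
3. **incomplete_taxonomy** — remove records whose lineage has empty
   ranks or a placeholder species epithet ("sp.", "cf." ...).
4. **chlorophyta** — remove green-algae records (any rank equal,
   case-insensitively, to Chlorophyta) from the vascular-plant set.
5. **intraspecific** — per species with at least ``min_species_n``
   members, walk an increasing drop-out ladder of median-identity
   thresholds (50, 75, 80, 85, 90, 92.5, 95, 97%), at each step
   removing members whose median identity to the other remaining
   members falls strictly below the threshold. Mode A applies only the
   top threshold in a single pass; mode B walks the full ladder; mode C
   (default) walks the ladder under a safeguard that keeps at least
   half of the species' sequences.

The report bookkeeping mirrors the published summary-table shape:
per-stage removed counts, retained sequence/species counts, totals and
integer percent losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import IO, Iterable, Sequence

import numpy as np
import yaml

from .align import AlignParams, best_hit, identity, identity_matrix
from .classify import build_index, classify, is_fungal, record_seed
from .taxfasta import DEFAULT_PLACEHOLDER_EPITHETS, Dataset, SeqRecord

_EPS = 1e-9

STAGES = (
    "fungal",
    "non_target",
    "incomplete_taxonomy",
    "chlorophyta",
    "intraspecific",
)


@dataclass
class CurationConfig:
    """Every numeric knob of the automated curation, with its default."""

    fungal_cutoff: float = 0.90
    fungal_decision_rank: str = "genus"
    nontarget_min_identity: float = 0.70
    chlorophyta_name: str = "Chlorophyta"
    ladder: tuple[float, ...] = (0.50, 0.75, 0.80, 0.85, 0.90, 0.925, 0.95, 0.97)
    min_species_n: int = 5
    safeguard_fraction: float = 0.50
    safeguard_basis: str = "initial"  # "initial" | "remaining"
    dropout_mode: str = "C"  # "A" | "B" | "C"
    recompute_medians: bool = True
    classifier_k: int = 8
    classifier_n_boot: int = 100
    classifier_subsample: int = 32
    seed: int = 42
    align_params: AlignParams = field(default_factory=AlignParams)
    placeholder_epithets: frozenset[str] = DEFAULT_PLACEHOLDER_EPITHETS

    def __post_init__(self) -> None:
        lad = tuple(self.ladder)
        if any(b <= a for a, b in zip(lad, lad[1:])) or not all(
            0 < t <= 1 for t in lad
        ):
            raise ValueError("ladder must be strictly increasing within (0, 1]")
        if not 0 < self.safeguard_fraction < 1:
            raise ValueError("safeguard_fraction must be in (0, 1)")
        if self.min_species_n < 2:
            raise ValueError("min_species_n must be >= 2")
        if self.dropout_mode not in ("A", "B", "C"):
            raise ValueError("dropout_mode must be A, B or C")
        if self.safeguard_basis not in ("initial", "remaining"):
            raise ValueError("safeguard_basis must be 'initial' or 'remaining'")

    @classmethod
    def from_yaml(cls, path: str) -> "CurationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        align_keys = {f.name for f in fields(AlignParams)}
        ap = {k: raw.pop(k) for k in list(raw) if k in align_keys}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ladder" in raw:
            raw["ladder"] = tuple(raw["ladder"])
        if "placeholder_epithets" in raw:
            raw["placeholder_epithets"] = frozenset(raw["placeholder_epithets"])
        kwargs = dict(raw)
        if ap:
            kwargs["align_params"] = AlignParams(**ap)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name not in ("align_params", "placeholder_epithets")
        }
        d["ladder"] = list(self.ladder)
        d["placeholder_epithets"] = sorted(self.placeholder_epithets)
        d.update(
            {
                f.name: getattr(self.align_params, f.name)
                for f in fields(AlignParams)
            }
        )
        return d


@dataclass
class RemovedRecord:
    accession: str
    stage: str
    reason: str
    detail: str


@dataclass
class StageEntry:
    stage: str
    removed: list[RemovedRecord]
    removed_count: int
    retained_sequences: int
    retained_species: int


@dataclass
class FilterReport:
    """Per-stage removed/retained bookkeeping for one curation run."""

    start_sequences: int
    start_species: int
    stages: list[StageEntry] = field(default_factory=list)
    final_species: int | None = None
    manual_removed: int = 0
    manual_added: int = 0

    def add_stage(
        self, stage: str, removed: list[RemovedRecord], ds_after: Dataset
    ) -> None:
        self.stages.append(
            StageEntry(
                stage=stage,
                removed=removed,
                removed_count=len(removed),
                retained_sequences=len(ds_after),
                retained_species=ds_after.n_species(),
            )
        )
        self.final_species = ds_after.n_species()

    @classmethod
    def from_counts(
        cls,
        start_sequences: int,
        start_species: int,
        stage_removals: Sequence[int],
        final_species: int,
    ) -> "FilterReport":
        """Build a report from bare counts (e.g. a published table)."""
        rep = cls(start_sequences=start_sequences, start_species=start_species)
        retained = start_sequences
        for stage, n in zip(STAGES, stage_removals):
            retained -= n
            rep.stages.append(
                StageEntry(
                    stage=stage,
                    removed=[],
                    removed_count=n,
                    retained_sequences=retained,
                    retained_species=-1,
                )
            )
        rep.final_species = final_species
        return rep

    @property
    def total_removed(self) -> int:
        return sum(s.removed_count for s in self.stages)

    @property
    def retained_sequences(self) -> int:
        if self.stages:
            return self.stages[-1].retained_sequences
        return self.start_sequences

    def validate(self) -> None:
        prev = self.start_sequences
        seen: set[str] = set()
        for s in self.stages:
            if s.removed and len(s.removed) != s.removed_count:
                raise ValueError(f"stage {s.stage}: removed list/count mismatch")
            if s.removed_count + s.retained_sequences != prev:
                raise ValueError(f"stage {s.stage}: conservation violated")
            accs = {r.accession for r in s.removed}
            if accs & seen:
                raise ValueError(f"stage {s.stage}: accession removed twice")
            seen |= accs
            prev = s.retained_sequences


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(report: FilterReport) -> dict:
    """Render the summary-table arithmetic of a report.

    Returns start counts, per-stage removed/retained, totals, integer
    percent losses (half-up rounding) for sequences and species, and the
    manual-curation arithmetic when the report carries it.
    """
    report.validate()
    total = report.total_removed
    retained = report.retained_sequences
    seq_loss = _round_half_up(100.0 * total / report.start_sequences) if report.start_sequences else 0
    if report.final_species is not None and report.final_species >= 0:
        species_removed = report.start_species - report.final_species
    else:
        species_removed = 0
    sp_loss = (
        _round_half_up(100.0 * species_removed / report.start_species)
        if report.start_species
        else 0
    )
    return {
        "start_sequences": report.start_sequences,
        "start_species": report.start_species,
        "stages": [
            {
                "stage": s.stage,
                "removed": s.removed_count,
                "retained_sequences": s.retained_sequences,
                "retained_species": s.retained_species,
            }
            for s in report.stages
        ],
        "total_removed": total,
        "retained_sequences": retained,
        "retained_species": report.final_species,
        "species_removed": species_removed,
        "sequence_loss_percent": seq_loss,
        "species_loss_percent": sp_loss,
        "after_manual_list": retained - report.manual_removed,
        "final_sequences": retained - report.manual_removed + report.manual_added,
    }


def write_summary_tsv(summary: dict, stream: IO[str]) -> None:
    stream.write("step\tremoved\tretained_sequences\tretained_species\n")
    stream.write(
        f"start\t\t{summary['start_sequences']}\t{summary['start_species']}\n"
    )
    for s in summary["stages"]:
        sp = s["retained_species"] if s["retained_species"] >= 0 else ""
        stream.write(f"{s['stage']}\t{s['removed']}\t{s['retained_sequences']}\t{sp}\n")
    stream.write(
        f"total\t{summary['total_removed']}\t{summary['retained_sequences']}\t"
        f"{summary['retained_species'] if summary['retained_species'] is not None else ''}\n"
    )
    stream.write(
        f"sequence_loss_percent\t{summary['sequence_loss_percent']}\t\t\n"
    )
    stream.write(f"species_loss_percent\t{summary['species_loss_percent']}\t\t\n")


def write_removed_tsv(report: FilterReport, stream: IO[str]) -> None:
    """Full list of removed accessions with stage, reason and detail."""
    stream.write("accession\tstage\treason\tdetail\n")
    for s in report.stages:
        for r in s.removed:
            stream.write(f"{r.accession}\t{r.stage}\t{r.reason}\t{r.detail}\n")


# ---------------------------------------------------------------------------
# individual filters


def filter_fungal(
    ds: Dataset, fungal_ref: Dataset, cfg: CurationConfig
) -> tuple[Dataset, list[RemovedRecord]]:
    """Remove sequences confidently classified as fungal."""
    if len(ds) == 0:
        return ds, []
    if len(fungal_ref) == 0:
        raise ValueError("fungal filter requires a non-empty fungal reference")
    idx = build_index(fungal_ref, k=cfg.classifier_k)
    removed: list[RemovedRecord] = []
    keep: list[SeqRecord] = []
    for rec in ds:
        c = classify(
            rec,
            idx,
            n_boot=cfg.classifier_n_boot,
            subsample=cfg.classifier_subsample,
            seed=record_seed(cfg.seed, rec.accession),
        )
        if is_fungal(c, cfg.fungal_cutoff, cfg.fungal_decision_rank):
            removed.append(
                RemovedRecord(
                    rec.accession,
                    "fungal",
                    "classified_as_fungal",
                    f"genus={c.names['genus']};confidence="
                    f"{c.confidences[cfg.fungal_decision_rank]:.2f}",
                )
            )
        else:
            keep.append(rec)
    return Dataset(keep), removed


def filter_nontarget(
    ds: Dataset, trusted_ref: Dataset, cfg: CurationConfig
) -> tuple[Dataset, list[RemovedRecord]]:
    """Remove sequences without a >= 70% identity hit in the trusted set."""
    if len(trusted_ref) == 0:
        raise ValueError("non-target filter requires a non-empty trusted reference")
    removed: list[RemovedRecord] = []
    keep: list[SeqRecord] = []
    for rec in ds:
        hit = best_hit(
            rec, trusted_ref, cfg.nontarget_min_identity, cfg.align_params
        )
        if hit is None:
            best = max(
                identity(rec.sequence, ref.sequence, cfg.align_params)
                for ref in trusted_ref
            )
            removed.append(
                RemovedRecord(
                    rec.accession,
                    "non_target",
                    "below_identity_threshold",
                    f"best_identity={best:.3f}",
                )
            )
        else:
            keep.append(rec)
    return Dataset(keep), removed


def filter_incomplete_taxonomy(
    ds: Dataset, cfg: CurationConfig | None = None
) -> tuple[Dataset, list[RemovedRecord]]:
    """Remove records with empty ranks or placeholder species epithets."""
    placeholders = (
        cfg.placeholder_epithets if cfg is not None else DEFAULT_PLACEHOLDER_EPITHETS
    )
    removed: list[RemovedRecord] = []
    keep: list[SeqRecord] = []
    for rec in ds:
        missing = rec.taxonomy.missing_ranks(placeholders)
        if missing:
            removed.append(
                RemovedRecord(
                    rec.accession,
                    "incomplete_taxonomy",
                    "incomplete_taxonomy",
                    "missing=" + ",".join(missing),
                )
            )
        else:
            keep.append(rec)
    return Dataset(keep), removed


def filter_chlorophyta(
    ds: Dataset, cfg: CurationConfig | None = None
) -> tuple[Dataset, list[RemovedRecord]]:
    """Remove green-algae records (any rank named Chlorophyta)."""
    name = (cfg.chlorophyta_name if cfg is not None else "Chlorophyta").lower()
    removed: list[RemovedRecord] = []
    keep: list[SeqRecord] = []
    for rec in ds:
        ranks = [r.lower() for r in rec.taxonomy.as_tuple()]
        if name in ranks:
            removed.append(
                RemovedRecord(
                    rec.accession, "chlorophyta", "chlorophyta_lineage", f"name={name}"
                )
            )
        else:
            keep.append(rec)
    return Dataset(keep), removed


def ladder_dropout(
    identity: np.ndarray, mode: str, cfg: CurationConfig
) -> tuple[list[int], list[tuple[int, float, float]]]:
    """Core drop-out logic on a precomputed identity matrix.

    Returns (kept indices, removed entries) where each removed entry is
    ``(index, threshold, median_at_removal)``. A median within 1e-9 of a
    threshold counts as *not* below it (strict inequality). Medians are
    recomputed over the surviving set after every ladder step (the
    pairwise identities themselves never change, so the cached matrix is
    reused).

    Mode A: single pass at the top ladder threshold, initial medians.
    Mode B: full ladder, no safeguard; a species reduced below two
    survivors stops its ladder.
    Mode C: as B, but a step is skipped — and the ladder stopped — if it
    would breach the retention safeguard (with basis ``initial``: leave
    fewer than ceil(safeguard_fraction x initial n) sequences; with
    basis ``remaining``: remove at least safeguard_fraction of the
    currently remaining ones).
    """
    n = identity.shape[0]

    def medians(current: list[int]) -> dict[int, float]:
        sub = identity[np.ix_(current, current)]
        out = {}
        for pos, i in enumerate(current):
            others = np.delete(sub[pos], pos)
            out[i] = float(np.median(others))
        return out

    if mode == "A":
        top = cfg.ladder[-1]
        med = medians(list(range(n)))
        removed = [(i, top, med[i]) for i in range(n) if med[i] < top - _EPS]
        gone = {i for i, _, _ in removed}
        return [i for i in range(n) if i not in gone], removed

    remaining = list(range(n))
    removed: list[tuple[int, float, float]] = []
    med = medians(remaining)
    for t in cfg.ladder:
        if len(remaining) < 2:
            break
        if cfg.recompute_medians:
            med = medians(remaining)
        drop = [i for i in remaining if med[i] < t - _EPS]
        if not drop:
            continue
        if mode == "C":
            if cfg.safeguard_basis == "initial":
                floor = math.ceil(cfg.safeguard_fraction * n)
                if len(remaining) - len(drop) < floor:
                    break
            else:  # remaining
                if len(drop) >= cfg.safeguard_fraction * len(remaining) - _EPS:
                    break
        removed.extend((i, t, med[i]) for i in drop)
        remaining = [i for i in remaining if i not in set(drop)]
    return remaining, removed


def filter_intraspecific(
    ds: Dataset, cfg: CurationConfig
) -> tuple[Dataset, list[RemovedRecord]]:
    """Per-species median-identity drop-out ladder (filter 5).

    Only species represented by at least ``min_species_n`` sequences are
    assessed; smaller species are left untouched.
    """
    removed: list[RemovedRecord] = []
    drop_accs: set[str] = set()
    for species, members in ds.species_index().items():
        if len(members) < cfg.min_species_n:
            continue
        mat = identity_matrix(members, cfg.align_params)
        _, gone = ladder_dropout(mat, cfg.dropout_mode, cfg)
        for i, t, med in gone:
            rec = members[i]
            drop_accs.add(rec.accession)
            removed.append(
                RemovedRecord(
                    rec.accession,
                    "intraspecific",
                    "high_intraspecific_variability",
                    f"species={species};median_identity={med:.3f};threshold={t:g}",
                )
            )
    return ds.without(drop_accs), removed


_FILTERS = {
    "fungal": lambda ds, fungal_ref, trusted_ref, cfg: filter_fungal(ds, fungal_ref, cfg),
    "non_target": lambda ds, fungal_ref, trusted_ref, cfg: filter_nontarget(ds, trusted_ref, cfg),
    "incomplete_taxonomy": lambda ds, fungal_ref, trusted_ref, cfg: filter_incomplete_taxonomy(ds, cfg),
    "chlorophyta": lambda ds, fungal_ref, trusted_ref, cfg: filter_chlorophyta(ds, cfg),
    "intraspecific": lambda ds, fungal_ref, trusted_ref, cfg: filter_intraspecific(ds, cfg),
}


def run_pipeline(
    ds: Dataset,
    fungal_ref: Dataset | None,
    trusted_ref: Dataset | None,
    cfg: CurationConfig,
    skip: Iterable[str | int] = (),
) -> tuple[Dataset, FilterReport]:
    """Apply the five filters in fixed order and report per-stage counts.

    ``skip`` may contain stage names or 1-based stage numbers. The
    corresponding reference dataset is only required for stages that
    actually run.
    """
    skip_names = {STAGES[s - 1] if isinstance(s, int) else s for s in skip}
    unknown = skip_names - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages to skip: {sorted(unknown)}")
    report = FilterReport(start_sequences=len(ds), start_species=ds.n_species())
    current = ds
    for stage in STAGES:
        if stage in skip_names:
            continue
        if stage == "fungal" and (fungal_ref is None or len(fungal_ref) == 0):
            if len(current) == 0:
                report.add_stage(stage, [], current)
                continue
            raise ValueError("fungal reference required unless stage 1 is skipped")
        if stage == "non_target" and (trusted_ref is None or len(trusted_ref) == 0):
            raise ValueError("trusted reference required unless stage 2 is skipped")
        current, removed = _FILTERS[stage](current, fungal_ref, trusted_ref, cfg)
        report.add_stage(stage, removed, current)
    report.validate()
    return current, report
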