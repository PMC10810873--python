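"""Seeded synthetic fixtures: references and "dirty" datasets with ground truth.

The generator stands in for a real marker download: it emits a trusted
plant reference set (one exemplar per family), a fungal reference set,
and a dataset of per-species sequence clusters into which known
contaminants of every filter class are planted — fungal copies wearing
plant labels, random non-target sequences, incomplete lineages,
green-algae labels, and intraspecific outliers. A manifest records
exactly which accession belongs to which category, so filter outcomes
can be checked against ground truth.

Margins are enforced at generation time (identities re-measured with the
package's own aligner, classifier confidences re-measured with its own
classifier) and offending pieces are regenerated, so that every planted
contaminant sits far from its filter's decision threshold and test
outcomes cannot hinge on alignment minutiae. Mutation is
substitution-only by default, keeping identity arithmetic predictable.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .align import DEFAULT_PARAMS, AlignParams, identity, identity_matrix
from .classify import build_index, classify
from .taxfasta import Dataset, SeqRecord, TaxonomyString, dump_taxfasta

_BASES = "ACGT"


class FixtureError(RuntimeError):
    """Requested fixture parameters cannot satisfy the margin assertions."""


@dataclass(frozen=True)
class FixtureParams:
    """Counts, rates and margins for the dirty-dataset generator."""

    n_clean_species: int = 50
    min_cluster: int = 2
    max_cluster: int = 10
    n_fungal: int = 5
    n_nontarget: int = 10
    n_incomplete: int = 3
    n_chlorophyta: int = 2
    n_outliers: int = 4
    length: int = 300
    species_divergence: float = 0.05  # species base vs family exemplar
    clean_mutation: float = 0.005  # member vs species base
    contaminant_mutation: float = 0.01  # planted fungal vs source reference
    indel_rate: float = 0.0
    max_retries: int = 30
    # margin assertions, all >= 0.08 away from the decision thresholds
    clean_median_floor: float = 0.975  # above the ladder's 0.97 top step
    outlier_median_ceiling: float = 0.62  # below every informative ladder step
    nontarget_identity_ceiling: float = 0.62  # below the 0.70 floor
    target_identity_floor: float = 0.78  # above the 0.70 floor
    fungal_confidence_floor: float = 0.95  # above the 0.90 cutoff
    clean_confidence_ceiling: float = 0.50  # below the 0.90 cutoff


CATEGORIES = ("fungal", "nontarget", "incomplete", "chlorophyta", "intraspecific_outlier")

#: category name -> pipeline stage at which its members must be removed
CATEGORY_STAGE = {
    "fungal": "fungal",
    "nontarget": "non_target",
    "incomplete": "incomplete_taxonomy",
    "chlorophyta": "chlorophyta",
    "intraspecific_outlier": "intraspecific",
}


@dataclass
class FixtureManifest:
    seed: int
    categories: dict[str, list[str]]
    clean: list[str]
    params: dict = field(default_factory=dict)

    def all_planted(self) -> set[str]:
        return {a for accs in self.categories.values() for a in accs}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        return cls(**json.loads(text))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(seq: str, substitution_rate: float, seed) -> str:
    """Substitute each position independently (to a different base).

    ``seed`` may be an int or a numpy Generator. Length is preserved.
    """
    if not 0 <= substitution_rate <= 1:
        raise ValueError("substitution rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = list(seq)
    hit = np.nonzero(rng.random(len(chars)) < substitution_rate)[0]
    for i in hit:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _plant_lineage(i: int) -> TaxonomyString:
    return TaxonomyString(
        kingdom="Viridiplantae",
        phylum="Streptophyta",
        class_="Magnoliopsida",
        order=f"Ordino{i:02d}ales",
        family=f"Familia{i:02d}ceae",
        genus=f"Typogen{i:02d}",
        species=f"Typogen{i:02d}_typus",
    )


def _fungal_lineage(i: int) -> TaxonomyString:
    phylum = "Ascomycota" if i % 2 == 0 else "Basidiomycota"
    return TaxonomyString(
        kingdom="Fungi",
        phylum=phylum,
        class_=f"Fungiclass{i:02d}",
        order=f"Fungord{i:02d}ales",
        family=f"Fungfam{i:02d}aceae",
        genus=f"Fungen{i:02d}",
        species=f"Fungen{i:02d}_typus",
    )


def make_references(
    seed: int,
    n_plant_families: int = 12,
    n_fungal_refs: int = 20,
    length: int = 300,
    params: AlignParams = DEFAULT_PARAMS,
    max_retries: int = 30,
) -> tuple[Dataset, Dataset]:
    """Trusted plant exemplars (one per family) and a fungal reference set.

    Generation asserts the identity margins (pairwise within-set
    identities < 0.7, cross-set < 0.6) and regenerates colliding
    entries; the same seed always yields byte-identical references.
    """
    if n_plant_families < 1 or n_fungal_refs < 1:
        raise ValueError("reference counts must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(accept) -> str:
        for _ in range(max_retries):
            seq = random_sequence(rng, length)
            if accept(seq):
                return seq
        raise FixtureError("could not satisfy reference identity margins")

    trusted: list[SeqRecord] = []
    for i in range(n_plant_families):
        seq = draw(
            lambda s: all(identity(s, r.sequence, params) < 0.7 for r in trusted)
        )
        trusted.append(SeqRecord(f"TRUST{i + 1:04d}", _plant_lineage(i), seq))
    fungal: list[SeqRecord] = []
    for i in range(n_fungal_refs):
        seq = draw(
            lambda s: all(identity(s, r.sequence, params) < 0.7 for r in fungal)
            and all(identity(s, r.sequence, params) < 0.6 for r in trusted)
        )
        fungal.append(SeqRecord(f"FUNREF{i + 1:04d}", _fungal_lineage(i), seq))
    return Dataset(trusted), Dataset(fungal)


def _clean_lineage(i: int, exemplar: TaxonomyString) -> TaxonomyString:
    return exemplar.replace(
        genus=f"Genus{i:03d}", species=f"Genus{i:03d}_species{i:03d}"
    )


def make_dirty_dataset(
    seed: int,
    trusted_ref: Dataset,
    fungal_ref: Dataset,
    params: FixtureParams = FixtureParams(),
) -> tuple[Dataset, FixtureManifest]:
    """Dataset of clean species clusters with planted contaminants.

    Every record belongs to exactly one manifest category (clean or one
    of the planted classes); each planted contaminant is asserted to sit
    beyond its margin so the corresponding filter must remove it — and
    nothing else — when the pipeline runs.
    """
    rng = np.random.default_rng(seed)
    ap = DEFAULT_PARAMS
    exemplars = list(trusted_ref)
    fungals = list(fungal_ref)
    if params.n_outliers > params.n_clean_species:
        raise FixtureError("cannot plant more outliers than clean species")
    kidx = build_index(fungal_ref, k=8)

    def not_fungal_like(seq: str) -> bool:
        c = classify(seq, kidx, seed=int(rng.integers(1 << 31)))
        return c.confidences["genus"] < params.clean_confidence_ceiling

    # entries: (taxonomy, sequence, category)
    entries: list[tuple[TaxonomyString, str, str]] = []

    for i in range(params.n_clean_species):
        exemplar = exemplars[i % len(exemplars)]
        with_outlier = i < params.n_outliers
        lo = max(params.min_cluster, 5) if with_outlier else params.min_cluster
        size = int(rng.integers(lo, params.max_cluster + 1))
        lineage = _clean_lineage(i, exemplar.taxonomy)
        for _ in range(params.max_retries):
            base = mutate(exemplar.sequence, params.species_divergence, rng)
            members = [mutate(base, params.clean_mutation, rng) for _ in range(size)]
            if with_outlier:
                foreign = exemplars[(i + 1 + len(exemplars) // 2) % len(exemplars)]
                outlier_seq = mutate(foreign.sequence, 0.02, rng)
            mat = identity_matrix(
                [SeqRecord(f"t{j}", lineage, m) for j, m in enumerate(members)], ap
            )
            medians = [
                float(np.median(np.delete(mat[j], j))) for j in range(size)
            ]
            ok = min(medians) > params.clean_median_floor
            ok = ok and all(
                identity(m, exemplar.sequence, ap)
                >= params.target_identity_floor
                for m in members
            )
            if ok and with_outlier:
                out_ids = [identity(outlier_seq, m, ap) for m in members]
                ok = (
                    float(np.median(out_ids)) < params.outlier_median_ceiling
                    and identity(outlier_seq, foreign.sequence, ap)
                    >= params.target_identity_floor
                )
            if ok:
                break
        else:
            raise FixtureError(f"margins unsatisfiable for clean species {i}")
        for m in members:
            entries.append((lineage, m, "clean"))
        if with_outlier:
            entries.append((lineage, outlier_seq, "intraspecific_outlier"))

    for i in range(params.n_fungal):
        src = fungals[int(rng.integers(len(fungals)))]
        exemplar = exemplars[int(rng.integers(len(exemplars)))]
        lineage = exemplar.taxonomy.replace(
            genus=f"Fakegen{i:02d}", species=f"Fakegen{i:02d}_impostor{i:02d}"
        )
        for _ in range(params.max_retries):
            seq = mutate(src.sequence, params.contaminant_mutation, rng)
            c = classify(seq, kidx, seed=int(rng.integers(1 << 31)))
            if (
                c.names["kingdom"] == "Fungi"
                and c.confidences["genus"] >= params.fungal_confidence_floor
            ):
                break
        else:
            raise FixtureError("planted fungal sequence fails confidence margin")
        entries.append((lineage, seq, "fungal"))

    for i in range(params.n_nontarget):
        exemplar = exemplars[int(rng.integers(len(exemplars)))]
        lineage = exemplar.taxonomy.replace(
            genus=f"Offgen{i:02d}", species=f"Offgen{i:02d}_alienum{i:02d}"
        )
        for _ in range(params.max_retries):
            seq = random_sequence(rng, params.length)
            best = max(
                identity(seq, r.sequence, ap) for r in exemplars
            )
            if best < params.nontarget_identity_ceiling and not_fungal_like(seq):
                break
        else:
            raise FixtureError("planted non-target fails identity margin")
        entries.append((lineage, seq, "nontarget"))

    incomplete_variants = ("family", "order", "placeholder")
    for i in range(params.n_incomplete):
        exemplar = exemplars[int(rng.integers(len(exemplars)))]
        seq = mutate(exemplar.sequence, 0.03, rng)
        variant = incomplete_variants[i % len(incomplete_variants)]
        lineage = exemplar.taxonomy.replace(
            genus=f"Incgen{i:02d}", species=f"Incgen{i:02d}_lacuna{i:02d}"
        )
        if variant == "placeholder":
            lineage = lineage.replace(species=f"Incgen{i:02d}_sp")
        else:
            lineage = lineage.replace(**{variant: ""})
        entries.append((lineage, seq, "incomplete"))

    for i in range(params.n_chlorophyta):
        exemplar = exemplars[int(rng.integers(len(exemplars)))]
        seq = mutate(exemplar.sequence, 0.03, rng)
        lineage = TaxonomyString(
            kingdom="Viridiplantae",
            phylum="Chlorophyta",
            class_="Chlorophyceae",
            order=f"Algord{i:02d}ales",
            family=f"Algfam{i:02d}aceae",
            genus=f"Alggen{i:02d}",
            species=f"Alggen{i:02d}_viridis{i:02d}",
        )
        entries.append((lineage, seq, "chlorophyta"))

    order = rng.permutation(len(entries))
    records: list[SeqRecord] = []
    categories: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    clean: list[str] = []
    for ordinal, idx in enumerate(order, start=1):
        lineage, seq, category = entries[idx]
        acc = f"SYN{ordinal:05d}"
        records.append(SeqRecord(acc, lineage, seq))
        if category == "clean":
            clean.append(acc)
        else:
            categories[category].append(acc)
    for accs in categories.values():
        accs.sort()
    manifest = FixtureManifest(
        seed=seed,
        categories=categories,
        clean=sorted(clean),
        params=dataclasses.asdict(params),
    )
    return Dataset(records), manifest


def write_fixture_bundle(
    out_dir: str,
    seed: int,
    params: FixtureParams = FixtureParams(),
    n_plant_families: int = 12,
    n_fungal_refs: int = 20,
) -> dict[str, str]:
    """Emit the full offline test bundle into a directory.

    Files: dirty dataset + both references (taxonomy FASTA), a taxonomy
    lookup TSV, a flora checklist CSV, a sample manual-curation list,
    and the ground-truth manifest JSON. Deterministic under the seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    trusted, fungal = make_references(
        seed, n_plant_families=n_plant_families, n_fungal_refs=n_fungal_refs,
        length=params.length,
    )
    ds, manifest = make_dirty_dataset(seed, trusted, fungal, params)
    paths = {
        "dataset": os.path.join(out_dir, "dirty.fasta"),
        "trusted_ref": os.path.join(out_dir, "trusted_ref.fasta"),
        "fungal_ref": os.path.join(out_dir, "fungal_ref.fasta"),
        "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
        "flora": os.path.join(out_dir, "flora.csv"),
        "curation_list": os.path.join(out_dir, "curation_list.txt"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    dump_taxfasta(ds, paths["dataset"])
    dump_taxfasta(trusted, paths["trusted_ref"])
    dump_taxfasta(fungal, paths["fungal_ref"])

    species_seen: dict[str, TaxonomyString] = {}
    for rec in ds:
        if rec.taxonomy.is_complete():
            species_seen.setdefault(rec.taxonomy.species, rec.taxonomy)
    extra = [
        TaxonomyString(
            "Viridiplantae", "Streptophyta", "Magnoliopsida",
            f"Novordo{i:02d}ales", f"Novfam{i:02d}aceae",
            f"Novgen{i:02d}", f"Novgen{i:02d}_addendum{i:02d}",
        )
        for i in range(3)
    ]
    with open(paths["taxonomy"], "w") as fh:
        fh.write("kingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies\n")
        for tax in list(species_seen.values()) + extra:
            fh.write("\t".join(tax.as_tuple()) + "\n")

    species_names = sorted(species_seen)
    half = species_names[: max(1, len(species_names) // 2)]
    with open(paths["flora"], "w") as fh:
        fh.write("species\n")
        for name in half:
            fh.write(name.replace("_", " ") + "\n")
        fh.write("Absens imaginarius\n")

    clean_accs = manifest.clean
    with open(paths["curation_list"], "w") as fh:
        fh.write("# accession;wrong_name;corrected_name;curator\n")
        if clean_accs:
            sp = ds[clean_accs[0]].taxonomy.species.replace("_", " ")
            fh.write(f"{clean_accs[0]};{sp};{extra[0].species.replace('_', ' ')};FixtureCurator\n")
        if len(clean_accs) > 1:
            sp = ds[clean_accs[1]].taxonomy.species.replace("_", " ")
            fh.write(f"{clean_accs[1]};{sp};;FixtureCurator\n")

    with open(paths["manifest"], "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return paths
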