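"""Non-redundant gene-set construction and Ni-dependent marker-gene retrieval.

The marker set is the five Ni-dependent enzymes observed in rumen
metagenomes: urease (URE), bifunctional acetyl-CoA synthase/CO
dehydrogenase (ACS), [NiFe]-hydrogenase (HYD), glyoxalase I (GLO) and
lactate racemase (LAR).  A gene is a marker candidate when its KEGG
Orthology (KO) annotation belongs to one of these enzymes; candidates are
confirmed by local alignment against reference sequences, retained only
with identity > 0.85 and query coverage > 0.90 (strict).

The non-redundant (NR) gene set is built by greedy incremental clustering,
longest sequence first, joining a cluster at >= 90% identity over an
alignment covering >= 90% of the shorter sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import Align

from . import io as nio

__all__ = [
    "MarkerCatalog",
    "MarkerHit",
    "default_marker_catalog",
    "pairwise_identity_coverage",
    "cluster_nr",
    "find_marker_genes",
]

_KO_RE = re.compile(r"^K\d{5}$")
_VALID_CHARS = frozenset("ACGTN")

#: enzyme name -> KO ids, following the subunit/accessory/maturation genes
#: reported for rumen metagenomes (urease ureA-ureD/H, ACS/CODH subunits,
#: [NiFe]-hydrogenase maturation hypA-hypF, glyoxalase I gloA, lactate
#: racemase larA).
DEFAULT_ENZYME_KOS: dict[str, tuple[str, ...]] = {
    "URE": ("K01428", "K01429", "K01430", "K03188", "K03189", "K03190"),
    "ACS": ("K00192", "K00196", "K00198"),
    "HYD": ("K04651", "K04652", "K04653", "K04654", "K04655", "K04656"),
    "GLO": ("K01759",),
    "LAR": ("K22373",),
}


@dataclass(frozen=True)
class MarkerHit:
    """A retained match of a gene against a marker reference sequence."""

    gene_id: str
    enzyme: str
    ko: str
    reference_id: str
    identity: float
    coverage: float


@dataclass
class MarkerCatalog:
    """Reference catalog of marker enzymes: KO membership plus sequences.

    ``references`` maps enzyme name -> {reference_id: sequence}.
    """

    enzyme_kos: dict[str, tuple[str, ...]]
    references: dict[str, dict[str, str]]
    _ko_to_enzyme: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for enzyme, kos in self.enzyme_kos.items():
            if not kos:
                raise ValueError(f"enzyme {enzyme} has no KO ids")
            for ko in kos:
                if not _KO_RE.match(ko):
                    raise ValueError(f"malformed KO id '{ko}' under enzyme {enzyme}")
                if ko in seen:
                    raise ValueError(
                        f"KO {ko} appears under both {seen[ko]} and {enzyme}"
                    )
                seen[ko] = enzyme
            if not self.references.get(enzyme):
                raise ValueError(f"enzyme {enzyme} has no reference sequence")
        self._ko_to_enzyme = seen

    @property
    def ko_to_enzyme(self) -> dict[str, str]:
        return dict(self._ko_to_enzyme)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "MarkerCatalog":
        """Load a catalog from a YAML manifest.

        Schema: ``enzymes: {NAME: {kos: [...], fasta: <path>}}`` with FASTA
        paths resolved relative to the manifest.
        """
        path = Path(path)
        data = nio.load_yaml(path)
        if "enzymes" not in data:
            raise ValueError(f"{path}: manifest missing 'enzymes' section")
        enzyme_kos, references = {}, {}
        for name, entry in data["enzymes"].items():
            enzyme_kos[name] = tuple(entry["kos"])
            references[name] = nio.read_fasta(path.parent / entry["fasta"])
        return cls(enzyme_kos, references)

    def to_manifest(self, directory: str | Path, name: str = "catalog") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"enzymes": {}}
        for enzyme, kos in self.enzyme_kos.items():
            fasta = f"{name}_{enzyme}.fasta"
            nio.write_fasta(directory / fasta, self.references[enzyme])
            manifest["enzymes"][enzyme] = {"kos": list(kos), "fasta": fasta}
        out = directory / f"{name}.yaml"
        import yaml

        out.write_text(yaml.safe_dump(manifest, sort_keys=True))
        return out


def default_marker_catalog(reference_length: int = 900) -> MarkerCatalog:
    """Build the bundled marker catalog.

    The enzyme→KO mapping is the real one; the reference sequences are
    synthetic stand-ins (deterministic random nucleotide sequences, one per
    KO), suitable for simulation and testing but not for annotating real
    data — point ``MarkerCatalog.from_manifest`` at a curated FASTA set for
    that.
    """
    rng = np.random.default_rng(20201222)
    bases = np.array(list("ACGT"))
    references: dict[str, dict[str, str]] = {}
    for enzyme, kos in DEFAULT_ENZYME_KOS.items():
        references[enzyme] = {
            f"{enzyme}_{ko}_ref": "".join(
                bases[rng.integers(0, 4, reference_length)]
            )
            for ko in kos
        }
    return MarkerCatalog(dict(DEFAULT_ENZYME_KOS), references)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence: {label}")
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence {label}")
    return seq


def pairwise_identity_coverage(query: str, subject: str) -> tuple[float, float]:
    """Best-scoring local alignment identity and query coverage.

    Identity is matches / aligned columns (gap columns included); coverage
    is the aligned span of the query divided by the query length.  Scoring:
    match +1, mismatch -1, gap open -2, gap extend -0.5.

    Co-optimal local alignments are tie-broken by aligning a canonical
    orientation (longer sequence as target, lexicographic on ties), which
    makes identity symmetric; coverage stays query-relative.
    """
    query = _check_sequence(query, "query")
    subject = _check_sequence(subject, "subject")
    if (len(subject), subject) >= (len(query), query):
        target, other, query_role = subject, query, 1
    else:
        target, other, query_role = query, subject, 0
    alignment = _ALIGNER.align(target, other)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    # aligned blocks of whichever role the caller's query occupies
    blocks = alignment.aligned[query_role]
    if len(blocks) == 0:
        return 0.0, 0.0
    span = int(blocks[-1][1] - blocks[0][0])
    return identity, span / len(query)


def cluster_nr(
    sequences: Mapping[str, str],
    identity_threshold: float = 0.90,
    coverage_threshold: float = 0.90,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy incremental clustering into a non-redundant gene set.

    Sequences are processed longest-first (ties broken lexicographically by
    id).  A sequence joins the first existing cluster whose representative
    aligns at ``identity >= identity_threshold`` with the alignment covering
    ``>= coverage_threshold`` of the shorter sequence; otherwise it founds a
    new cluster.  Returns ``(representatives, member_map)`` where
    ``member_map`` maps every input id to its representative id.
    """
    for sid, seq in sequences.items():
        _check_sequence(seq, sid)
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    representatives: dict[str, str] = {}
    member_map: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        placed = False
        for rep_id, rep_seq in representatives.items():
            # processed longest-first, so the candidate is never longer
            identity, coverage = pairwise_identity_coverage(seq, rep_seq)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                member_map[sid] = rep_id
                placed = True
                break
        if not placed:
            representatives[sid] = seq
            member_map[sid] = sid
    return representatives, member_map


def find_marker_genes(
    nr_genes: Mapping[str, str],
    ko_map: Mapping[str, str],
    catalog: MarkerCatalog,
    min_identity: float = 0.85,
    min_coverage: float = 0.90,
) -> list[MarkerHit]:
    """Identify marker genes by KO gate plus identity/coverage matching.

    Candidate genes are those whose KO belongs to a catalog enzyme; each is
    aligned against that enzyme's references and retained iff the best hit
    has identity strictly > ``min_identity`` and query coverage strictly
    > ``min_coverage``.  One hit (the best reference) per gene.
    """
    ko_to_enzyme = catalog.ko_to_enzyme
    missing = [g for g, ko in ko_map.items() if ko in ko_to_enzyme and g not in nr_genes]
    if missing:
        raise ValueError(f"gene(s) in KO map absent from NR gene set: {sorted(missing)}")
    hits: list[MarkerHit] = []
    for gene_id in sorted(g for g, ko in ko_map.items() if ko_map[g] in ko_to_enzyme):
        ko = ko_map[gene_id]
        enzyme = ko_to_enzyme[ko]
        best: tuple[float, float, str] | None = None
        for ref_id, ref_seq in catalog.references[enzyme].items():
            identity, coverage = pairwise_identity_coverage(nr_genes[gene_id], ref_seq)
            key = (identity, coverage, ref_id)
            if best is None or key > best:
                best = key
        assert best is not None
        identity, coverage, ref_id = best
        if identity > min_identity and coverage > min_coverage:
            hits.append(MarkerHit(gene_id, enzyme, ko, ref_id, identity, coverage))
    return hits


def write_marker_hits(path: str | Path, hits: list[MarkerHit]) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (h.gene_id, h.enzyme, h.ko, h.reference_id, h.identity, h.coverage)
            for h in hits
        ],
        columns=["gene_id", "enzyme", "ko", "reference_id", "identity", "coverage"],
    )
    nio.write_table(path, df)
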