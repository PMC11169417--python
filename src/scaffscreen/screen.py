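"""Hierarchical two-round scaffold-first virtual screening.

Round 1 scores one representative per scaffold (the bare scaffold by
default, optionally methyl-capped) and selects the best ``top_k``.  Round 2
scores the sub-library of all library members of the selected scaffolds,
applies a residue-interaction filter (pass iff a pose contacts at least
``min_required_matches`` of the required residues), and returns ranked hits.

Scoring is a pluggable contract: any callable object with
``score(mol, seed, n_poses) -> (list of pose scores, InteractionReport)``
that is deterministic given (canonical structure, seed).  Lower scores are
better (docking-energy convention).  External docking programs plug in via
JSON pose reports; the deterministic SyntheticScorer here rewards planted
pharmacophore substructures and emits contacts for them, which is what makes
the whole funnel testable without a docking license.

The default residue set is the voltage-sensor site's binding hot spots
Tyr1537, Trp1538, Arg1602, Arg1608 with min_matches 2; both are
configuration, not constants of the method.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .enumeration import LibraryRecord, canonical_smiles
from .scaffolds import ScaffoldIndex, extract_sublibrary

logger = logging.getLogger("scaffscreen.screen")

DEFAULT_REQUIRED_RESIDUES = frozenset({"Tyr1537", "Trp1538", "Arg1602", "Arg1608"})
INTERACTION_CLASSES = ("pi_pi", "cation_pi", "hbond", "ionic", "hydrophobic")

__all__ = [
    "ScoreRecord",
    "InteractionReport",
    "CampaignConfig",
    "HitTable",
    "SyntheticScorer",
    "score_candidates",
    "interaction_filter",
    "hierarchical_screen",
    "DEFAULT_REQUIRED_RESIDUES",
]


@dataclass(frozen=True)
class InteractionReport:
    """Residue contacts of one pose: list of (residue label, class)."""

    record_id: str
    pose_id: int
    contacts: tuple[tuple[str, str], ...] = ()

    @property
    def residues(self) -> frozenset[str]:
        return frozenset(res for res, _cls in self.contacts)


@dataclass(frozen=True)
class ScoreRecord:
    record_id: str
    score: float  # best (minimum) pose score; lower = better
    n_poses_evaluated: int
    best_pose_id: int
    report: InteractionReport | None = None
    status: str = "OK"  # or SCORE_FAIL


@dataclass
class CampaignConfig:
    """Round policies for a two-round campaign."""

    round1_top_k: int = 3
    round2_top_k: int = 50
    required_residues: frozenset[str] = DEFAULT_REQUIRED_RESIDUES
    min_required_matches: int = 2
    n_poses: int = 30
    seed: int = 0
    cap_scaffold: bool = False  # score a methyl-capped representative in round 1

    def __post_init__(self):
        if self.round1_top_k < 1 or self.round2_top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_required_matches > len(self.required_residues):
            raise ValueError("min_required_matches exceeds |required_residues|")


@dataclass
class HitTable:
    """Output of a campaign: per-round selections plus a reconciling audit log."""

    round1_selected: list[tuple[str, float]]  # (scaffold key, score)
    round2_hits: list[ScoreRecord]
    audit: dict = field(default_factory=dict)


def _stable_seed(smiles: str, seed: int, pose: int) -> int:
    h = hashlib.sha256(f"{smiles}|{seed}|{pose}".encode()).digest()
    return int.from_bytes(h[:4], "big")


class SyntheticScorer:
    """Deterministic substructure-pharmacophore scorer for testing campaigns.

    score = -(sum of weight x match count over motifs) + seeded per-pose
    jitter ~ N(0, jitter_sd).  Motifs map to residue contacts so the
    interaction filter is exercisable.  Deterministic given (canonical
    SMILES, seed): repeated calls are bit-identical.
    """

    def __init__(
        self,
        motifs: list[tuple[str, float, list[tuple[str, str]]]] | None = None,
        jitter_sd: float = 0.0,
    ):
        # default motif: any aromatic nitrogen -> pi contacts at the hot spots
        self.motifs = motifs or [
            ("[n]", 1.0, [("Tyr1537", "pi_pi"), ("Trp1538", "pi_pi"), ("Arg1602", "cation_pi")]),
        ]
        self.jitter_sd = float(jitter_sd)
        self._queries = [
            (Chem.MolFromSmarts(patt), weight, contacts)
            for patt, weight, contacts in self.motifs
        ]

    def score(
        self, mol: Chem.Mol, seed: int, n_poses: int = 1
    ) -> tuple[list[float], InteractionReport]:
        smi = canonical_smiles(mol)
        base = 0.0
        contacts: list[tuple[str, str]] = []
        for query, weight, motif_contacts in self._queries:
            n = len(mol.GetSubstructMatches(query))
            base -= weight * n
            if n:
                contacts.extend(motif_contacts)
        scores = []
        for pose in range(n_poses):
            if self.jitter_sd > 0:
                rng = np.random.default_rng(_stable_seed(smi, seed, pose))
                scores.append(base + self.jitter_sd * rng.standard_normal())
            else:
                scores.append(base)
        best = int(np.argmin(scores))
        # deduplicate contacts, stable order
        uniq = tuple(dict.fromkeys(contacts))
        return scores, InteractionReport(record_id=smi, pose_id=best, contacts=uniq)


def score_candidates(
    candidates: list[tuple[str, Chem.Mol]],
    scorer,
    n_poses: int = 30,
    seed: int = 0,
) -> list[ScoreRecord]:
    """Score each candidate, keeping the best (minimum) of n_poses pose scores.

    A scorer failure flags the record SCORE_FAIL and excludes it from
    ranking; it never aborts the batch.
    """
    out = []
    for cid, mol in candidates:
        try:
            pose_scores, report = scorer.score(mol, seed=seed, n_poses=n_poses)
        except Exception as exc:  # noqa: BLE001 - contract: flag, don't abort
            logger.warning("scorer failed on %s: %s", cid, exc)
            out.append(
                ScoreRecord(
                    record_id=cid, score=float("nan"), n_poses_evaluated=0,
                    best_pose_id=-1, status="SCORE_FAIL",
                )
            )
            continue
        best = int(np.argmin(pose_scores))
        out.append(
            ScoreRecord(
                record_id=cid,
                score=float(pose_scores[best]),
                n_poses_evaluated=len(pose_scores),
                best_pose_id=best,
                report=InteractionReport(
                    record_id=cid, pose_id=best, contacts=report.contacts
                ),
            )
        )
    return out


def interaction_filter(
    report: InteractionReport,
    required: frozenset[str] | set[str],
    min_matches: int,
) -> tuple[bool, frozenset[str]]:
    """Pass iff the pose contacts at least min_matches required residues."""
    matched = report.residues & frozenset(required)
    return len(matched) >= min_matches, matched


def _rank(records: list[ScoreRecord]) -> list[ScoreRecord]:
    """Strict deterministic ranking: (score, record id) ascending."""
    ok = [r for r in records if r.status == "OK"]
    return sorted(ok, key=lambda r: (r.score, r.record_id))


def hierarchical_screen(
    index: ScaffoldIndex,
    records: list[LibraryRecord],
    config: CampaignConfig,
    scorer,
) -> HitTable:
    """Run the two-round scaffold-first campaign.

    Fully reproducible given (inputs, config, seed).  An empty round-1
    selection returns an empty HitTable with a warning, never an error.
    """
    # --- round 1: score one representative per scaffold key
    reps: list[tuple[str, Chem.Mol]] = []
    for key in index.keys:
        if key == "ACYCLIC":
            continue
        mol = Chem.MolFromSmiles(key)
        if mol is None:
            continue
        if config.cap_scaffold:
            capped = Chem.MolFromSmiles(key)  # placeholder copy; caps below
            mol = _methyl_cap(capped) or mol
        reps.append((key, mol))
    r1_scores = score_candidates(reps, scorer, n_poses=config.n_poses, seed=config.seed)
    r1_ranked = _rank(r1_scores)
    selected = r1_ranked[: config.round1_top_k]
    selected_keys = {r.record_id for r in selected}
    if not selected:
        logger.warning("hierarchical_screen: empty round-1 selection")
        return HitTable(round1_selected=[], round2_hits=[], audit={"round1_scored": len(reps)})

    # --- round 2: score the sub-library of the selected scaffolds
    sub = extract_sublibrary(index, selected_keys, records)
    candidates = [(r.record_id, r.mol) for r in sub]
    r2_scores = score_candidates(candidates, scorer, n_poses=config.n_poses, seed=config.seed)
    rejections: dict[str, str] = {}
    passed: list[ScoreRecord] = []
    for rec in r2_scores:
        if rec.status != "OK":
            rejections[rec.record_id] = "SCORE_FAIL"
            continue
        ok, matched = interaction_filter(
            rec.report, config.required_residues, config.min_required_matches
        )
        if ok:
            passed.append(rec)
        else:
            rejections[rec.record_id] = (
                f"interaction_filter: matched {sorted(matched)} "
                f"< min {config.min_required_matches} of {sorted(config.required_residues)}"
            )
    hits = _rank(passed)[: config.round2_top_k]
    audit = {
        "round1_scored": len(reps),
        "round1_selected": sorted(selected_keys),
        "round2_scored": len(candidates),
        "round2_expected": sum(len(index.members(k)) for k in selected_keys),
        "round2_passed_filter": len(passed),
        "round2_hits": len(hits),
        "rejections": rejections,
    }
    return HitTable(
        round1_selected=[(r.record_id, r.score) for r in selected],
        round2_hits=hits,
        audit=audit,
    )


def _methyl_cap(scaffold: Chem.Mol) -> Chem.Mol | None:
    """Methyl-capped scaffold representative: a CH3 on the first open site."""
    from .scaffolds import _attachment_sites  # local to avoid cycle at import

    sites = _attachment_sites(scaffold, None)
    if not sites:
        return None
    rw = Chem.RWMol(scaffold)
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(sites[0], c, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # noqa: BLE001
        return None
    return mol
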