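"""Downstream quantities from per-site amino-acid profiles.

* **network energy** E: sum over scorable sites of the wild-type amino acid's
  pseudoenergy; Delta E measures the response to a structural perturbation.
* **mutation scores** Delta log P = log P_mut - log P_wt (natural log), a proxy
  for the stability change of a point mutation.  Sign convention: *positive*
  means the mutant amino acid fits its neighborhood better than the wild type
  does (destabilising mutations score negative).  In ``paired_structures`` mode
  the mutant probability is evaluated on the mutant structure; in ``wt_only``
  mode both probabilities come from the wild-type neighborhood.
* **profile overlap**: centered cosine similarity of two 20-vectors of
  probabilities (1 = identical shape, 0 = unrelated, -1 = anti-correlated).
* **confusion matrix**: mean predicted probability vector conditioned on the
  true central amino acid.
* **ensembling**: arithmetic mean of per-model log probabilities, after which
  any of the scores above are recomputed from the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .holograms import encode
from .network import AA_ALPHABET, AAProfile, CGNetwork
from .structure import Structure, extract_neighborhoods

logger = logging.getLogger(__name__)

__all__ = [
    "MutationSpec",
    "MutationScore",
    "site_profiles",
    "network_energy",
    "score_mutation",
    "profile_overlap",
    "confusion_matrix",
    "ensemble_log_probabilities",
]


@dataclass(frozen=True)
class MutationSpec:
    """A point mutation in author numbering: chain, site, wt 1-letter, mutant 1-letter."""

    chain: str
    site: int
    wt_aa: str
    mut_aa: str
    ins_code: str = ""

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_ALPHABET:
                raise ValueError(f"{aa!r} is not a standard 1-letter amino acid")

    def __str__(self):
        return f"{self.wt_aa}{self.site}{self.mut_aa}"


@dataclass
class MutationScore:
    variant: MutationSpec
    delta_log_p: float
    mode: str  # "paired_structures" | "wt_only"


def _prepare(model: CGNetwork, structure: Structure) -> Structure:
    from .structure import annotate
    needs = bool({"charge", "SASA"} & set(model.channels))
    if needs and not structure.is_annotated:
        annotate(structure)
    return structure


def site_profiles(
    model: CGNetwork, structure: Structure
) -> list[tuple[tuple[str, int, str], str, AAProfile]]:
    """Predict an amino-acid profile for every scorable site of a structure.

    Returns (residue_id, true 1-letter label, profile) triples; residues whose
    label is outside the model's alphabet are skipped with a log message.
    """
    structure = _prepare(model, structure)
    nbs = extract_neighborhoods(structure, radius=model.basis.r_max,
                                channels=model.channels)
    keep = [nb for nb in nbs if nb.label in model.alphabet]
    skipped = len(nbs) - len(keep)
    if skipped:
        logger.info("%d sites outside the model alphabet skipped", skipped)
    if not keep:
        raise ValueError("no scorable sites in structure")
    coeffs = [encode(nb, model.basis) for nb in keep]
    logits = model.predict_batch(coeffs)
    return [
        (nb.focal_residue, nb.label, AAProfile(logits[j], alphabet=model.alphabet))
        for j, nb in enumerate(keep)
    ]


def network_energy(model: CGNetwork, structure: Structure) -> float:
    """E = sum over sites of the wild-type amino acid's pseudoenergy."""
    profs = site_profiles(model, structure)
    return float(sum(p.pseudoenergy(label) for _, label, p in profs))


def _profile_at(model: CGNetwork, structure: Structure, spec: MutationSpec) -> AAProfile:
    structure = _prepare(model, structure)
    i = structure.find_residue(spec.chain, spec.site, spec.ins_code)
    nbs = extract_neighborhoods(structure, radius=model.basis.r_max,
                                channels=model.channels)
    target = structure.residue_id(i)
    for nb in nbs:
        if nb.focal_residue == target:
            return model.forward(encode(nb, model.basis))
    raise ValueError(f"site {target} has no extractable neighborhood")


def score_mutation(
    model: CGNetwork,
    wt_structure: Structure,
    mut_structure: Structure | None,
    spec: MutationSpec,
) -> MutationScore:
    """Delta log P for one point mutation (natural logarithm).

    With ``mut_structure`` given: log P(mut_aa | mutant-structure neighborhood)
    minus log P(wt_aa | wild-type neighborhood).  Without it (``wt_only``):
    both probabilities are evaluated on the wild-type neighborhood.
    """
    i = wt_structure.find_residue(spec.chain, spec.site, spec.ins_code)
    found = wt_structure.residue_label(i)
    if found != spec.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {spec.chain}/{spec.site}: structure has "
            f"{found!r}, spec says {spec.wt_aa!r}"
        )
    wt_prof = _profile_at(model, wt_structure, spec)
    if mut_structure is None:
        dlp = wt_prof.log_probability(spec.mut_aa) - wt_prof.log_probability(spec.wt_aa)
        return MutationScore(spec, float(dlp), "wt_only")
    mut_prof = _profile_at(model, mut_structure, spec)
    dlp = mut_prof.log_probability(spec.mut_aa) - wt_prof.log_probability(spec.wt_aa)
    return MutationScore(spec, float(dlp), "paired_structures")


def profile_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Centered cosine similarity of two equal-length probability profiles."""
    p = np.asarray(p, dtype=float).reshape(-1)
    q = np.asarray(q, dtype=float).reshape(-1)
    if p.shape != q.shape:
        raise ValueError("profiles must have equal length")
    pc = p - p.mean()
    qc = q - q.mean()
    np_, nq = np.linalg.norm(pc), np.linalg.norm(qc)
    if np_ < 1e-12 or nq < 1e-12:
        raise ValueError("profile overlap undefined for a constant profile")
    return float(np.dot(pc, qc) / (np_ * nq))


def confusion_matrix(
    profiles: list[AAProfile],
    labels: list[str],
    alphabet: str = AA_ALPHABET,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean predicted probabilities conditioned on the true central residue.

    Returns ``(matrix, counts)``: row g of ``matrix`` is the mean probability
    vector over samples whose true label is ``alphabet[g]`` (NaN for labels
    with zero samples, reported in ``counts``).
    """
    if not profiles:
        raise ValueError("no profiles given")
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels differ in length")
    k = len(alphabet)
    sums = np.zeros((k, k))
    counts = np.zeros(k, dtype=int)
    for prof, lab in zip(profiles, labels):
        if lab not in alphabet:
            raise ValueError(f"label {lab!r} outside alphabet")
        g = alphabet.index(lab)
        sums[g] += prof.probabilities
        counts[g] += 1
    matrix = np.full((k, k), np.nan)
    nz = counts > 0
    matrix[nz] = sums[nz] / counts[nz, None]
    if not nz.all():
        logger.info("confusion matrix rows with zero samples: %s",
                    [alphabet[g] for g in np.nonzero(~nz)[0]])
    return matrix, counts


def ensemble_log_probabilities(per_model: list[np.ndarray]) -> np.ndarray:
    """Average predicted log probabilities over an ensemble of models.

    ``per_model`` holds one (n_sites, n_aa) array of log probabilities per
    model, all over the same site set; returns their arithmetic mean.
    Downstream scores are then recomputed from the averaged values.
    """
    if not per_model:
        raise ValueError("empty ensemble")
    arrs = [np.asarray(a, dtype=float) for a in per_model]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("inconsistent site sets across ensemble members")
    return np.mean(arrs, axis=0)
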