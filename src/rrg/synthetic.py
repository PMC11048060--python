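"""Synthetic chest-radiograph / findings-report corpus generator.

Emulates the study structure of chest report-generation datasets at desk
scale: each study holds 1–3 grayscale views, a latent per-pathology status
(present / absent / uncertain / unmentioned), a multi-sentence templated
findings report with paraphrase and sentence-order variability, and the
ground-truth entity/relation graph of that report.

The image encodes the finding statuses geometrically so that pixels alone
determine the mentioned findings: every pathology owns a fixed grid cell in
which its glyph is drawn solid at full intensity when present, solid at half
intensity when uncertain, and as a hollow outline when explicitly absent;
unmentioned pathologies leave the cell at background.  Extra views are
affine-jittered copies carrying a distinct corner marker.  Rendered pixels
are quantized to the 8-bit grid so the corpus round-trips losslessly through
PNG storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from . import language
from .metrics import Entity, EntityGraph, Relation
from .text import Report

BACKGROUND = 0.1
GLYPH_HIGH = 0.9           # solid glyph intensity for "present"
GLYPH_HALF = 0.5           # solid glyph intensity for "uncertain"
INTENSITY_GAP = GLYPH_HIGH - GLYPH_HALF
OUTLINE_WIDTH_FRAC = 0.125  # outline ring thickness, fraction of cell size
MARKER_INTENSITY_STEP = 0.25
JITTER_PX = 2.0
RESAMPLE_LIMIT = 100
GRID = 4                   # pathology sites live on a GRID x GRID cell layout


class GenerationError(RuntimeError):
    """Raised when corpus generation cannot satisfy its constraints."""


DEFAULT_PREVALENCE: dict[str, float] = {
    "present": 0.3,
    "absent": 0.3,
    "uncertain": 0.1,
    "unmentioned": 0.3,
}


@dataclass
class CorpusConfig:
    """Generation conditions for one synthetic corpus."""

    n_train: int = 200
    n_validation: int = 40
    n_test: int = 40
    k_pathologies: int = 6
    image_size: int = 64
    noise_amplitude: float = 0.05
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))

    def __post_init__(self):
        if self.k_pathologies < 1:
            raise GenerationError("k_pathologies must be >= 1")
        if self.k_pathologies > GRID * GRID - 1:
            raise GenerationError(
                f"at most {GRID * GRID - 1} pathology sites are available")
        if self.image_size % GRID:
            raise GenerationError(f"image_size must be divisible by {GRID}")

    @property
    def pathologies(self) -> tuple[str, ...]:
        return language.default_pathologies(self.k_pathologies)


@dataclass
class Study:
    study_id: str
    images: list[np.ndarray]
    findings: dict[str, str]
    report: Report
    graph: EntityGraph

    def __post_init__(self):
        if not 1 <= len(self.images) <= 3:
            raise ValueError("a study holds 1-3 images")

    def __eq__(self, other):
        if not isinstance(other, Study):
            return NotImplemented
        return (self.study_id == other.study_id
                and len(self.images) == len(other.images)
                and all(np.array_equal(a, b) for a, b in zip(self.images, other.images))
                and self.findings == other.findings
                and self.report == other.report
                and self.graph == other.graph)


@dataclass
class CorpusSplit:
    train: list[Study]
    validation: list[Study]
    test: list[Study]
    seed: int
    template_bank_version: str = language.TEMPLATE_BANK_VERSION

    def all_studies(self) -> list[Study]:
        return [*self.train, *self.validation, *self.test]

    def __eq__(self, other):
        if not isinstance(other, CorpusSplit):
            return NotImplemented
        return (self.seed == other.seed
                and self.template_bank_version == other.template_bank_version
                and self.train == other.train
                and self.validation == other.validation
                and self.test == other.test)


# --------------------------------------------------------------------- sampling

def _validate_prevalence(prevalence: Mapping[str, float]) -> None:
    if set(prevalence) != set(language.STATUSES):
        raise GenerationError(
            f"prevalence must cover statuses {language.STATUSES}")
    total = sum(prevalence.values())
    if any(v < 0 for v in prevalence.values()) or abs(total - 1.0) > 1e-9:
        raise GenerationError("prevalence probabilities must be >= 0 and sum to 1")


def sample_findings(rng: np.random.Generator, k_pathologies: int,
                    prevalence_table: Mapping[str, float] | None = None
                    ) -> dict[str, str]:
    """Draw an independent status per pathology; resample (up to a limit)
    until at least one finding is mentioned — studies with empty findings
    are never emitted."""
    if k_pathologies < 1:
        raise GenerationError("k_pathologies must be >= 1")
    prevalence = dict(prevalence_table or DEFAULT_PREVALENCE)
    _validate_prevalence(prevalence)
    pathologies = language.default_pathologies(k_pathologies)
    statuses = list(language.STATUSES)
    probs = np.array([prevalence[s] for s in statuses])
    for _ in range(RESAMPLE_LIMIT):
        draw = rng.choice(len(statuses), size=k_pathologies, p=probs)
        findings = {p: statuses[i] for p, i in zip(pathologies, draw)}
        if any(s != "unmentioned" for s in findings.values()):
            return findings
    raise GenerationError(
        f"no mentioned finding after {RESAMPLE_LIMIT} resamples; "
        "prevalence leaves too little mass off 'unmentioned'")


# -------------------------------------------------------------------- rendering

def _site_cells() -> list[tuple[int, int]]:
    """Row-major grid cells, excluding the (0, 0) view-marker corner."""
    return [(r, c) for r in range(GRID) for c in range(GRID) if (r, c) != (0, 0)]


def pathology_site(index: int, image_size: int) -> tuple[slice, slice]:
    """Pixel-slice of the glyph square for pathology `index`."""
    cs = image_size // GRID
    r, c = _site_cells()[index]
    m = max(cs // 8, 1)
    return (slice(r * cs + m, (r + 1) * cs - m),
            slice(c * cs + m, (c + 1) * cs - m))


def glyph_interior(index: int, image_size: int) -> tuple[slice, slice]:
    """Glyph square minus the outline ring (solid-fill region)."""
    cs = image_size // GRID
    w = max(int(cs * OUTLINE_WIDTH_FRAC), 1)
    rs, cs_ = pathology_site(index, image_size)
    return slice(rs.start + w, rs.stop - w), slice(cs_.start + w, cs_.stop - w)


def _render_base(findings: Mapping[str, str], image_size: int) -> np.ndarray:
    img = np.full((image_size, image_size), BACKGROUND)
    for i, patho in enumerate(language.default_pathologies(len(findings))):
        status = findings[patho]
        site = pathology_site(i, image_size)
        if status == "present":
            img[site] = GLYPH_HIGH
        elif status == "uncertain":
            img[site] = GLYPH_HALF
        elif status == "absent":
            img[site] = GLYPH_HIGH
            img[glyph_interior(i, image_size)] = BACKGROUND
    return img


def render_views(findings: Mapping[str, str], n_views: int,
                 rng: np.random.Generator, image_size: int = 64,
                 noise_amplitude: float = 0.05) -> list[np.ndarray]:
    """Render 1-3 views of a study.

    View 0 is the canonical layout; further views are affine-jittered copies.
    Every view carries a corner marker whose intensity identifies the view.
    Output is clipped to [0, 1] and quantized to the 8-bit grid.
    """
    if not 1 <= n_views <= 3:
        raise ValueError("n_views must be in 1..3")
    base = _render_base(findings, image_size)
    cs = image_size // GRID
    views = []
    for v in range(n_views):
        img = base.copy()
        if v > 0:
            shift = rng.uniform(-JITTER_PX, JITTER_PX, size=2)
            img = ndimage.shift(img, shift, order=1, mode="nearest")
        img[2:cs - 2, 2:cs - 2] = MARKER_INTENSITY_STEP * (v + 1)
        img = img + rng.uniform(-noise_amplitude, noise_amplitude, img.shape)
        img = np.clip(img, 0.0, 1.0)
        views.append(np.round(img * 255.0) / 255.0)
    return views


def decode_findings_from_pixels(image: np.ndarray,
                                k_pathologies: int) -> dict[str, str]:
    """Hand-written inverse of the renderer (canonical, unjittered view).

    Classifies each pathology site from its interior and outline means; used
    to verify that the image alone determines the mentioned findings.
    """
    size = image.shape[0]
    out: dict[str, str] = {}
    for i, patho in enumerate(language.default_pathologies(k_pathologies)):
        interior = float(image[glyph_interior(i, size)].mean())
        site = float(image[pathology_site(i, size)].mean())
        ring = (site * 1.0)  # site mean includes the ring
        if interior > (GLYPH_HIGH + GLYPH_HALF) / 2:
            out[patho] = "present"
        elif interior > (GLYPH_HALF + BACKGROUND) / 2:
            out[patho] = "uncertain"
        elif ring > (GLYPH_HALF + BACKGROUND) / 2:
            out[patho] = "absent"
        else:
            out[patho] = "unmentioned"
    return out


# ---------------------------------------------------------------------- reports

SENTENCE_SWAP_PROB = 0.1


def realize_report(findings: Mapping[str, str], rng: np.random.Generator,
                   template_bank: Mapping[str, Sequence[str]] | None = None,
                   swap_prob: float = SENTENCE_SWAP_PROB
                   ) -> tuple[Report, EntityGraph]:
    """One sentence per mentioned finding, randomly perturbed habitual
    order, random paraphrase; plus the ground-truth entity/relation graph.

    Sentence order is randomized the way reporting style is in practice:
    writers follow a habitual ordering (here, the fixed pathology order)
    with occasional deviations, modelled as independent adjacent swaps with
    probability ``swap_prob``.  A low-entropy order distribution is what
    gives sentence-shuffling text augmentation something to add during
    training.
    """
    bank = dict(template_bank or language.TEMPLATES)
    for status in language.MENTIONED_STATUSES:
        if status not in bank or not bank[status]:
            raise GenerationError(f"template bank is missing status {status!r}")
    mentioned = [p for p, s in findings.items() if s != "unmentioned"]
    if not mentioned:
        raise GenerationError("cannot realize a report with no mentioned finding")
    order = list(range(len(mentioned)))
    for i in range(len(order) - 1):
        if rng.random() < swap_prob:
            order[i], order[i + 1] = order[i + 1], order[i]
    sentences: list[str] = []
    entities: set[Entity] = set()
    relations: set[Relation] = set()
    for idx in order:
        patho = mentioned[idx]
        status = findings[patho]
        templates = bank[status]
        template = templates[int(rng.integers(len(templates)))]
        anat = language.PATHOLOGY_ANATOMY[patho]
        sentences.append(template.format(obs=patho, anat=anat))
        obs_ent = Entity(patho, language.STATUS_TO_OBS_LABEL[status])
        anat_ent = Entity(anat, "ANAT-DP")
        entities.update((obs_ent, anat_ent))
        relations.add(Relation(obs_ent, anat_ent, "located_at"))
    report = Report.from_sentences(sentences)
    return report, EntityGraph(frozenset(entities), frozenset(relations))


# ----------------------------------------------------------------------- corpus

def generate_study(study_id: str, config: CorpusConfig,
                   rng: np.random.Generator) -> Study:
    findings = sample_findings(rng, config.k_pathologies, config.prevalence)
    n_views = int(rng.integers(1, 4))
    images = render_views(findings, n_views, rng, config.image_size,
                          config.noise_amplitude)
    report, graph = realize_report(findings, rng)
    return Study(study_id, images, findings, report, graph)


def generate_corpus(config: CorpusConfig, seed: int) -> CorpusSplit:
    """Deterministic corpus generation: same seed, byte-identical corpus."""
    rng = np.random.default_rng(seed)
    splits: dict[str, list[Study]] = {}
    for name, n in (("train", config.n_train),
                    ("validation", config.n_validation),
                    ("test", config.n_test)):
        splits[name] = [generate_study(f"{name}-{i:04d}", config, rng)
                        for i in range(n)]
    return CorpusSplit(splits["train"], splits["validation"], splits["test"],
                       seed=seed)


# ------------------------------------------------------------------------ disk

def _graph_to_json(graph: EntityGraph) -> dict:
    entities = sorted(graph.entities)
    index = {e: i for i, e in enumerate(entities)}
    relations = sorted((index[r.head], index[r.tail], r.type)
                       for r in graph.relations)
    return {"entities": [[e.text, e.label] for e in entities],
            "relations": [list(r) for r in relations]}


def _graph_from_json(d: dict) -> EntityGraph:
    entities = [Entity(t, l) for t, l in d["entities"]]
    relations = frozenset(Relation(entities[h], entities[t], typ)
                          for h, t, typ in d["relations"])
    return EntityGraph(frozenset(entities), relations)


def write_corpus(split: CorpusSplit, out_dir: str | Path,
                 force: bool = False) -> Path:
    """JSON Lines metadata per split plus one 8-bit grayscale PNG per view."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} exists and is not empty; pass force=True to overwrite")
    (out / "images").mkdir(parents=True, exist_ok=True)
    meta = {"seed": split.seed,
            "template_bank_version": split.template_bank_version}
    (out / "corpus.json").write_text(json.dumps(meta, sort_keys=True) + "\n")
    for name in ("train", "validation", "test"):
        lines = []
        for study in getattr(split, name):
            paths = []
            for v, img in enumerate(study.images):
                rel = f"images/{study.study_id}-{v}.png"
                arr = np.round(img * 255.0).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out / rel)
                paths.append(rel)
            lines.append(json.dumps({
                "study_id": study.study_id,
                "image_paths": paths,
                "report_text": study.report.text,
                "findings": study.findings,
                "graph": _graph_to_json(study.graph),
            }, sort_keys=True))
        (out / f"{name}.jsonl").write_text("\n".join(lines) + "\n")
    return out


def load_corpus(corpus_dir: str | Path) -> CorpusSplit:
    root = Path(corpus_dir)
    meta = json.loads((root / "corpus.json").read_text())
    splits: dict[str, list[Study]] = {}
    for name in ("train", "validation", "test"):
        studies = []
        for line in (root / f"{name}.jsonl").read_text().splitlines():
            d = json.loads(line)
            images = []
            for rel in d["image_paths"]:
                arr = np.asarray(Image.open(root / rel), dtype=np.float64)
                images.append(arr / 255.0)
            studies.append(Study(
                d["study_id"], images, dict(d["findings"]),
                Report.from_text(d["report_text"]),
                _graph_from_json(d["graph"])))
        splits[name] = studies
    return CorpusSplit(splits["train"], splits["validation"], splits["test"],
                       seed=meta["seed"],
                       template_bank_version=meta["template_bank_version"])
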