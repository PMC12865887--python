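# residuelink

Ground protein-residue mentions from full-text structural-biology
articles in the structures they describe.

Structural-biology papers discuss specific residues — "Arg155 forms a
salt bridge", "the R155A mutant lost activity" — but a reader has no
direct route from that sentence to the residue in the deposited PDB
entry, its position in the UniProt reference sequence, or the
experimental evidence behind it. `residuelink` implements the
annotation pipeline that closes that gap:

1. **Ingest** a JATS XML article into a sentence dictionary — one record
   per sentence with a stable 1-based identifier, section title, and
   character bounds (`char_start` always 0, `char_end` the sentence
   length).
2. **Tag** residue (`residue_name_number`) and point-mutation
   (`mutant`) mentions per sentence. The tagger is a pluggable backend;
   the shipped `reference` backend is a deterministic pattern matcher,
   so the pipeline runs with no model weights. Sentences are grouped
   8 per chunk, 4 chunks per batch (32 sentences), within a 512-token
   window.
3. **Harvest** predictions into standoff annotations in the Europe PMC
   submission style: `exact`, `position` (`"25.18"` = 18th word of the
   25th sentence), 30-character `prefix`/`postfix` context, `type`,
   `ai_score`, `char_start`/`char_end`, `tags` — fusing directly
   adjacent same-type spans first.
4. **Post-process** against amino-acid notation patterns: repair
   decorated spans (`Glu89H_complexB` → `Glu89`), expand one-letter
   codes (`R155A` → `Arg155Ala`), relabel when the notation contradicts
   the claimed type (setting `annotator: "post_processing"` and
   `ai_score: "removed"`), and discard spans that fit no pattern
   (`pET`).
5. **Link** each surviving mention to residues of the article's PDB
   entries via SIFTS residue-level mapping. A mention resolves when its
   number and amino acid agree with either the author (PDB) numbering
   or the UniProt reference numbering; author numbering takes priority.
6. **Enrich** each hit with per-residue quality metrics from the wwPDB
   validation report: Ramachandran class, rotamer, phi/psi, clashes,
   alternate conformations, plus RSCC (X-ray), Q-score (cryo-EM) or
   restraint violations (NMR).
7. **Write** one JSON document per article (schema shipped in
   `residuelink/schema/`). Closed-access articles keep only the two
   grounded entity types.

A SemEval-style scorer (strict / exact / partial / type schemes over
COR, INC, PAR, MIS, SPU counts, with `P = (COR + 0.5·PAR)/actual`,
`R = (COR + 0.5·PAR)/possible`, `F1 = 2PR/(P+R)`) and a synthetic
bundle generator with planted ground truth make every stage testable
offline.

## Worked example

Generate a synthetic bundle (article + SIFTS + validation XML with
planted mentions) and annotate it:

```python
from residuelink import fixtures, pipeline
from residuelink.fixtures import FixtureSpec
import json

bundle = fixtures.generate(FixtureSpec(seed=1))
data = pipeline.annotate_to_json(bundle.jats_xml, bundle.sifts_xml,
                                 bundle.validation_xml, bundle.lookup)
print(json.loads(data)["anns"][0])
```

prints (abridged):

```json
{
  "sid": 1,
  "exact": "Tyr81",
  "position": "1.8",
  "prefix": "s on the protonation state of ",
  "postfix": ".",
  "type": "residue_name_number",
  "ai_score": 1.0,
  "char_start": 46,
  "char_end": 51,
  "annotator": "model",
  "tags": [
    {
      "pdb_id": "3u2c",
      "pdb_res": "Tyr81",
      "pdb_chain": "A",
      "numbering_scheme": "pdb",
      "ramachandran": "OUTLIER",
      "rotamer": "m-80",
      "phi": "17.9",
      "psi": "12.4",
      "uniprot_id": "P25455",
      "uniprot_res": "Tyr91",
      "uniprot_uri": "https://www.uniprot.org/uniprotkb/P25455",
      "rscc": "0.70"
    }
  ]
}
```

Reading: the first sentence mentions `Tyr81` (its 8th word); the
residue exists as Tyr 81 in chain A of PDB entry 3u2c under author
numbering, maps to position 91 of UniProt P25455 (the synthetic entry
uses a +10 offset), and its density fit (RSCC 0.70) and geometry came
from the validation report.

The same run from the shell:

```sh
residuelink make-fixtures --seed 1 --out bundle/
residuelink annotate bundle/article.xml --sifts bundle/sifts \
    --validation bundle/validation --lookup bundle/lookup.json \
    --out annotations.json
residuelink evaluate bundle/gold.tsv annotations.json
```

The evaluation table reports precision, recall and F1 per scheme; on a
bundle with no unmatchable mentions every cell is 1.00.

## Layout

| module | role |
| --- | --- |
| `residuelink.jats` | JATS parsing, sentence segmentation, metadata enrichment |
| `residuelink.tagger` | backend registry, reference pattern tagger, batching |
| `residuelink.harvest` | position keys, context windows, adjacency merging |
| `residuelink.postprocess` | mention parsing, span repair, relabelling |
| `residuelink.sifts` | SIFTS parsing, mention resolution, tag assembly |
| `residuelink.validation` | wwPDB validation report parsing |
| `residuelink.annotation_io` | annotation JSON read/write + schema checks |
| `residuelink.semeval` | four-scheme NER scoring |
| `residuelink.fixtures` | synthetic bundle generator with gold |
| `residuelink.cli` | `residuelink annotate / evaluate / make-fixtures` |

See `docs/methods.md` for the underlying model of the problem, the
design choices and the known limitations.
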