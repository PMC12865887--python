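# Methods

## The problem and the pipeline's model of it

A residue mention in running text ("Arg155", "Phe 34", "R155A",
"Arg155Ala") carries three pieces of information: an amino-acid
identity, a sequence position, and — for point mutations — a second
amino-acid identity. Grounding such a mention in a structure requires
deciding *which numbering scheme the authors used*. Publications quote
either the author-assigned residue numbers of the deposited PDB entry
or the positions of the UniProt reference sequence; the two commonly
differ by a constant offset (expression tags, construct boundaries) and
occasionally by more. The pipeline therefore treats a mention as
resolvable exactly when its (number, amino acid) pair agrees with a
residue under one of the two schemes of the SIFTS residue-level
mapping, and unresolvable otherwise. Unresolvable mentions are real and
expected — authors sometimes use construct-local numbering matching
neither resource — and the pipeline's contract is to leave them
annotated but untagged (or drop them under `--drop-unlinked`), never to
guess.

The stages and their data contracts:

- **Sentence dictionary.** Articles are reduced to an ordered list of
  sentences, each with a 1-based id, section title and character
  bounds. All downstream offsets are sentence-relative, 0-based,
  half-open; `char_start` of a sentence is always 0 and `char_end` its
  character count. This makes annotations self-contained: an annotation
  plus its sentence id pinpoints text without re-parsing the article.
- **Standoff annotations.** Each annotation records the exact span, a
  `position` key `"<sid>.<word>"` (1-based, whitespace-delimited words;
  a span starting mid-word takes that word's index), up to 30
  characters of prefix/postfix context clipped at sentence bounds, the
  entity type from a closed 20-label vocabulary, the tagger confidence,
  and the structure associations under `tags`.
- **Grounded types.** Only `residue_name_number` and `mutant` are
  parsed, repaired and linked; the other 18 labels pass through the
  pipeline untouched and are kept only for open-access articles.

## Tagging

The tagger contract is a callable from sentence text to raw
predictions; any model can be registered. The shipped reference backend
is a deterministic maximal-match rule tagger over three patterns:
three-letter code + optional single space + 1–5 digit number
(residue), one-letter wt + number + one-letter substitute (mutation,
upper-case only, word-bounded), three-letter wt + number + three-letter
substitute (mutation). Overlaps resolve longest-first, leftmost on
ties, which reproduces the behaviour expected of span-maximising model
decoders. Rule matches are certain by construction, so the reference
backend reports confidence 1.0; confidence thresholds stay meaningful
for model backends.

Sentences are fed to backends in chunks of 8 and batches of 4 chunks
(32 sentences), mirroring how a 512-token encoder window is filled.
The token estimate is whitespace words × 1.5 — deliberately
conservative, since subword tokenisers emit more tokens than words; a
chunk whose estimate would overflow is split, and a single oversize
sentence is flagged for truncated prediction while its annotation
offsets keep referring to the full sentence.

## Post-processing

Parsing is anchored (full-span) and case-sensitive: three-letter codes
match `Arg` or `ARG` but never `arg`, one-letter codes upper-case only
— lowercase words like "his" must never parse. Sequence numbers are
restricted to 1–99999 (PDB numbering range). One-letter codes are
expanded to three-letter form, so every surviving mention normalises to
`Arg155` / `Arg155Ala`.

Three deliberate choices where the behaviour was genuinely open:

- **Repair strategy.** A failed span is repaired to the longest prefix
  that parses, then to the longest internal substring (leftmost on
  ties). This handles both decoration at the end (`Glu89H_complexB`,
  `Glu89H` → `Glu89`) and wrapping (`(Arg155)` → `Arg155`). Repairs
  shrink the span; the removed characters move into the context
  windows, so `prefix + exact + postfix` remains a contiguous substring
  of the sentence. Every repair is logged.
- **Mixed notation.** `Arg155A` is accepted as `Arg155Ala`, but only
  when the tagger already claims the `mutant` label. Unconditional
  acceptance would make a stray chain label parse as a substitution
  (`Glu89H` → `Glu89His`), which is the wrong reading in structural
  papers, where trailing capitals are usually chain or complex labels.
  Configurable off (`allow_mixed=False`).
- **Relabelling.** When the matched pattern contradicts the claimed
  type, the label is rewritten to the pattern's type, the annotator set
  to `post_processing`, and the confidence replaced by the sentinel
  string `"removed"` — the original model score no longer describes the
  (relabelled) annotation. Re-running post-processing is a no-op.

## Structure linking

`resolve_mention` scans all SIFTS residues and collects hits under both
schemes, then keeps only the highest-priority scheme with any hit
(author-PDB first by default; configurable). One result therefore never
mixes numbering schemes. Further choices:

- Mentions never carry insertion codes, so a mention matches author
  number *n* only where the insertion code is blank.
- For mutations the deposited structure may carry either the wild-type
  or the substituted residue at the position; both names are accepted
  under the author scheme. The UniProt reference sequence carries the
  wild type, so the UniProt scheme checks the wild-type name only. The
  tag records `wildtype_pdb_res` for mutants.
- Residues are deduplicated on (chain, author number) so multi-model
  (NMR) files yield one tag per residue; quality comes from model 1.
- Exactly one method-specific metric group appears per tag: `rscc`
  (X-ray), `q_score` (cryo-EM), or `distances`/`angles` (NMR). The
  experimental method comes from the validation report's entry element
  when available, else from metric presence, else from configuration.

Validation-report numeric fields are carried both as parsed floats and
as the printed strings, and the strings are what the tags re-emit —
re-serialisation must not change `0.70` into `0.7`.

## Serialisation and licensing

The annotation JSON is byte-stable (fixed key order, UTF-8) and checked
against the shipped JSON Schema on write and read; the schema validator
is implemented in-package (a small subset: type, enum, required,
properties, items, oneOf) and reports the JSON-pointer path of the
offending field. For articles that are not open access only the two
grounded entity types are written: emitting 30-character context for
all 20 types would expose large parts of a paywalled text, whereas the
two grounded types carry short notation strings. Whether their context
windows are also blanked is configurable (`blank_closed_context`);
default keeps them.

## The synthetic bundle generator

The generator emulates the coherent triplet a real run consumes —
article, SIFTS mapping, validation report — with planted ground truth.
Defaults: 40 sentences, half carrying exactly one mention; 30 % of
mentions are point mutations; 20 % of residue mentions are written with
a space ("Xxx N"); two chains of 120 residues; UniProt numbering offset
+10; 20 % of linkable mentions quote UniProt numbering; X-ray method;
open licence. These are the conditions under which the package's own
claims are measured; unmatchable mentions default to 0 and are enabled
per experiment.

Construction guarantees, not post-hoc filtering, make the gold exact:

- Amino-acid identities at planted positions agree across article,
  SIFTS and validation files. For a planted mutation the structure
  carries the substituted residue and the reference sequence the wild
  type.
- UniProt-numbered mentions are planted in the top `uniprot_offset`
  rows of a chain, so the quoted number exceeds the author range and
  can only resolve through the reference numbering.
- Unmatchable mentions quote numbers beyond both numbering ranges.
- Sentence templates contain no amino-acid codes, digits or
  abbreviations, so the reference tagger finds exactly the planted
  spans and the sentence splitter reproduces exactly the planted
  sentence boundaries.

What the generator does *not* emulate: tagger errors (the reference
backend is exact), sub-token span fragmentation, OCR noise, tables and
figure captions, multi-article structures, real SIFTS corner cases
(multi-segment chains, Pfam/CATH cross-references), and the statistics
of real entity co-occurrence. Passing planted-truth tests therefore
demonstrates the correctness of the plumbing — segmentation, offsets,
merging, parsing, resolution, accounting — not the recall of any
learned tagger on real prose.

## Evaluation

The scorer implements the four classic NER regimes over
COR/INC/PAR/MIS/SPU counts with `possible = COR+INC+PAR+MIS`,
`actual = COR+INC+PAR+SPU`, `P = (COR+0.5·PAR)/actual`,
`R = (COR+0.5·PAR)/possible`, `F1 = 2PR/(P+R)` (0 when `P+R = 0`).
Gold/pred pairing is greedy by overlap length with leftmost tie-break;
on span sets without internal overlaps (the precondition, enforced)
this equals the optimal assignment, which the tests verify against a
brute-force oracle on small instances. Both micro (pooled counts,
default) and macro (mean over types) averaging are provided.
Presentation rounding is half-up to 2 decimals; all internal arithmetic
is unrounded.

## Numerical and degenerate-input choices

- Sentence segmentation is rule-based (terminal punctuation + closing
  marks + whitespace + capital/digit opener) with a configurable
  protected-abbreviation list; deterministic and dependency-free.
- Empty paragraphs contribute no sentences; an article with no running
  text at all is an error distinct from malformed XML.
- Merged prediction confidence is the minimum of the members
  (conservative). "Directly adjacent" includes separation by
  whitespace only; strict character-touching mode is available.
- Duplicate validation-report residue keys: last wins, with a warning.
  Absent attributes stay empty — no value is ever fabricated.
- Unknown entity labels, malformed spans and out-of-range scores are
  rejected at construction time, not discovered downstream.

## Known limitations

- The reference tagger recognises notation, not context: it cannot find
  mentions written as prose ("the arginine at position 155") and never
  assigns the other 18 entity types, so end-to-end runs with it exercise
  only the grounded-type path.
- Repair candidates are substrings of the original span; a span missing
  characters (e.g. truncated by the tokeniser) cannot be repaired.
- Cross-sentence entities are out of scope; merging operates within a
  sentence.
- The SIFTS parser reads the per-entry residue-mapping dialect only;
  Pfam/CATH/SCOP cross-references are ignored.
- Scoring of archive-scale corpora (thousands of articles) is untested
  here; the package's measured claims are at synthetic-bundle scale
  (tens of sentences, hundreds of residues), which the acceptance
  script reproduces in seconds.
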