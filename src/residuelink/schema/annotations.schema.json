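{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "residuelink annotation document",
  "description": "One article's text-mined annotations in the Europe PMC submission style: provider and article identifiers at the top level, one entry per standoff annotation under 'anns', structure/UniProt associations under each annotation's 'tags'.",
  "type": "object",
  "required": ["provider", "doi", "licence", "pdb_ids", "anns"],
  "properties": {
    "provider": {"type": "string"},
    "doi": {"type": "string"},
    "pmid": {"type": ["string", "null"]},
    "pmcid": {"type": ["string", "null"]},
    "publisher_id": {"type": ["string", "null"]},
    "licence": {"enum": ["open", "closed", "unknown"]},
    "pdb_ids": {"type": "array", "items": {"type": "string"}},
    "organism_names": {"type": "array", "items": {"type": "string"}},
    "taxonomy_ids": {"type": "array", "items": {"type": "string"}},
    "uniprot_accessions": {"type": "array", "items": {"type": "string"}},
    "anns": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "sid",
          "exact",
          "position",
          "prefix",
          "postfix",
          "type",
          "ai_score",
          "char_start",
          "char_end",
          "annotator",
          "tags"
        ],
        "properties": {
          "sid": {"type": "integer"},
          "exact": {"type": "string"},
          "position": {"type": "string"},
          "prefix": {"type": "string"},
          "postfix": {"type": "string"},
          "type": {
            "enum": [
              "bond_interaction",
              "chemical",
              "complex_assembly",
              "evidence",
              "experimental_method",
              "gene",
              "mutant",
              "oligomeric_state",
              "protein",
              "protein_state",
              "protein_type",
              "ptm",
              "residue_name",
              "residue_number",
              "residue_name_number",
              "residue_range",
              "site",
              "species",
              "structure_element",
              "taxonomy_domain"
            ]
          },
          "ai_score": {"oneOf": [{"type": "number"}, {"enum": ["removed"]}]},
          "char_start": {"type": "integer"},
          "char_end": {"type": "integer"},
          "annotator": {"enum": ["model", "post_processing"]},
          "tags": {"type": "array", "items": {"type": "object"}}
        }
      }
    }
  }
}
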