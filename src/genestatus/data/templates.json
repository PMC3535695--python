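{
  "GENETIC_LESION_DETECTED": [
    {"template": "Positive {GENE} mutation test is required for enrollment .", "section": "eligibility"},
    {"template": "Patient with {GENE} positive disease confirmed by laboratory testing .", "section": "eligibility"},
    {"template": "Documented activating {GENE} mutation in tumor tissue .", "section": "summary"}
  ],
  "GENETIC_LESION_NOT_DETECTED": [
    {"template": "Patient must have wild type {GENE} confirmed by testing .", "section": "eligibility"},
    {"template": "Tumor shows negative staining for {GENE} on review .", "section": "eligibility"},
    {"template": "Absence of {GENE} rearrangement in the tumor specimen .", "section": "summary"}
  ],
  "GENETIC_LESION_MENTIONED": [
    {"template": "{GENE} gene analysis of archival tumor tissue will be performed .", "section": "summary"},
    {"template": "Mutational analysis of genes such as {GENE} is planned during screening .", "section": "eligibility"}
  ],
  "GENE_ONLY": [
    {"template": "{GENE} is a gene that codes for a receptor tyrosine kinase .", "section": "summary"},
    {"template": "{GENE} is a protein in cancer cells that regulates gene expression .", "section": "summary"}
  ],
  "DRUG": [
    {"template": "Prior treatment with {GENE} inhibitor chemotherapy is allowed .", "section": "eligibility"},
    {"template": "{GENE} peptide vaccination in carcinomas of the lung .", "section": "title"},
    {"template": "Subjects receiving {GENE} blocker therapy within four weeks are excluded .", "section": "eligibility"}
  ],
  "OTHERS": [
    {"template": "Criteria are {gene} before randomization can proceed .", "section": "eligibility"},
    {"template": "Samples processed using the {gene} and standard testing procedures .", "section": "summary"}
  ],
  "GENETIC_LESION_DETECTED_OR_NOT": [
    {"template": "Eligible if {GENE} status was determined prior to study entry .", "section": "eligibility"},
    {"template": "Known {GENE} result from an earlier assay satisfies screening either way .", "section": "eligibility"}
  ]
}
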