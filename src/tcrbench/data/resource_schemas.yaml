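# Example SchemaMaps for common public TCR-pMHC resource exports.
# Column names reflect typical flat exports; adjust to the exact
# export you downloaded (resources change their headers between
# releases).
- resource_id: vdjdb
  delimiter: "\t"
  column_map:
    cdr3.alpha: cdr3_alpha
    cdr3.beta: cdr3_beta
    antigen.epitope: peptide
    mhc.a: mhc
- resource_id: iedb
  delimiter: ","
  column_map:
    Chain 1 CDR3 Curated: cdr3_alpha
    Chain 2 CDR3 Curated: cdr3_beta
    Description: peptide
    MHC Allele Names: mhc
- resource_id: mcpas
  delimiter: ","
  column_map:
    CDR3.alpha.aa: cdr3_alpha
    CDR3.beta.aa: cdr3_beta
    Epitope.peptide: peptide
    MHC: mhc
- resource_id: immunecode
  delimiter: ","
  column_map:
    cdr3_amino_acid: cdr3_beta
    peptide: peptide
    hla: mhc
- resource_id: tbadb
  delimiter: "\t"
  column_map:
    CDR3.alpha: cdr3_alpha
    CDR3.beta: cdr3_beta
    Antigen: peptide
    HLA: mhc
- resource_id: tenx
  delimiter: ","
  column_map:
    cdr3_alpha: cdr3_alpha
    cdr3_beta: cdr3_beta
    antigen_peptide: peptide
    allele: mhc
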