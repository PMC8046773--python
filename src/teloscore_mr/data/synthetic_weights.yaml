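# SYNTHETIC per-allele effects of the 11 panel SNPs on leukocyte telomere
# length, in base pairs per long-telomere allele (beta_bp) with standard
# errors (se_bp).  These are NOT the published GWAS estimates: they are
# stand-in values with realistic magnitudes (about 50-120 bp per allele,
# z-scores near the genome-wide significance boundary) for simulation,
# testing and worked examples.  Replace with published values for any
# substantive analysis.
rs11125529: {beta_bp: 65.0, se_bp: 11.0}
rs6772228: {beta_bp: 120.0, se_bp: 20.0}
rs10936599: {beta_bp: 117.0, se_bp: 16.0}
rs7675998: {beta_bp: 74.0, se_bp: 12.0}
rs2736100: {beta_bp: 78.0, se_bp: 9.0}
rs9420907: {beta_bp: 69.0, se_bp: 12.0}
rs3027234: {beta_bp: 77.0, se_bp: 13.0}
rs8105767: {beta_bp: 48.0, se_bp: 8.0}
rs412658: {beta_bp: 89.0, se_bp: 15.0}
rs6028466: {beta_bp: 58.0, se_bp: 10.0}
rs755017: {beta_bp: 62.0, se_bp: 11.0}
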