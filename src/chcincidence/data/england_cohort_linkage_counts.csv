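cohort,live_births,hes_births,included
2002/3,565709,533406,423456
2003/4,589851,547636,485301
2004/5,607184,557927,508945
2005/6,613028,578446,533446
2006/7,635748,600595,557667
2007/8,655357,624933,562596
2008/9,672809,633574,594510
2009/10,671058,648371,625122
2010/11,687077,649636,628452
2011/12,688120,633670,618054
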