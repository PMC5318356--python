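study_id,year,design,blinding,treatment_1,treatment_2,size,male_pct,follow_up,endpoints
Silberstein2013,2013,parallel,double,gabapentin,placebo,523,21,20w,1;3;4;5;6;7;8;9
Afshari2012,2012,parallel,double,topiramate,valproate,56,21,12w,2;4;5;6;8;9
Lipton2011,2011,parallel,double,topiramate,placebo,330,13,26w,1;4;5;6;7;8;9
Holroyd2010,2010,parallel,double,propranolol,placebo,106,21,16m,1;8;9
Dodick2009,2009,parallel,double,topiramate,amitriptyline,346,15,26w,1;4;5;6;7;8;9
Ashtari2008,2008,parallel,double,topiramate,propranolol,62,21,8w,2;6;7;8;9
Silberstein2007,2007,parallel,double,topiramate,placebo,306,15,126d,1;4;5;6;7;8;9
Gupta2007,2007,crossover,double,topiramate,placebo,60,22,20w,1;4;8;9
Diener2007a,2007,parallel,double,topiramate,placebo,59,26,16w,1;4;5;6;7;8
Diener2007b,2007,parallel,double,topiramate,placebo,514,13,6m,1;4;5;7;8
Tommaso2007,2007,parallel,double,topiramate,placebo,30,22,1d,9
Silberstein2006,2006,parallel,double,topiramate,placebo,211,14,12w,4
Shaygannejad2006,2006,crossover,double,topiramate,valproate,64,57,24w,2;6
Brandes2006,2006,parallel,double,topiramate,placebo,468,13,13m,2;8;9
Silberstein2004,2004,parallel,double,topiramate,placebo,469,11,26w,1;2;3;5;6;8;9
Mei2004,2004,parallel,double,topiramate,placebo,115,46,16w,2;3;4;6;8;9
Diener2004,2004,parallel,double,topiramate,propranolol,568,20,1y,1;2;4;5;6;8;9
Brandes2004,2004,parallel,double,topiramate,placebo,483,13,26w,5;8;9
Freitag2002,2002,parallel,double,divalproex,placebo,237,21,12w,1;2;3;4;5;6;8;9
Storey2001,2001,parallel,double,topiramate,placebo,40,25,12w,2;3;8;9
Mathew2001,2001,parallel,double,gabapentin,placebo,143,17,16w,2;3;4;6;7;8;9
Klapper1997,1997,parallel,single,divalproex,placebo,176,12,12w,3;4;5;6;8;9
Kaniecki1997,1997,parallel,single,divalproex,propranolol,37,19,12w,4;5;7;9
Diener1996,1996,parallel,double,propranolol,placebo,133,22,12w,3;8;9
Bendtsen1996,1996,crossover,double,amitriptyline,placebo,40,38,32w,4;5;7;9
Mathew1995,1995,parallel,double,divalproex,placebo,107,20,12w,1;3;5;6;8;9
HeringKuritzky1992,1992,crossover,double,valproate,placebo,32,21,16w,5;7;9
Pradalier1989,1989,parallel,double,propranolol,placebo,74,24,16w,2;5;7;8;9
Mikkelsen1986,1986,crossover,double,propranolol,placebo,31,16,12w,4;8;9
Sadeghian2015,2015,parallel,double,valproate,placebo,58,27,6m,3;4;9
Sarchielli2014,2014,parallel,double,valproate,placebo,88,21,6m,4;5;7;8;9
Nofal2014,2014,parallel,double,gabapentin,placebo,86,0,4d,5;7
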