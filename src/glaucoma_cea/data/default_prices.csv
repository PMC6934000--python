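product_id,inn,drug_class,preservative_free,pack_price_bgn,doses_per_pack
pg_pf,latanoprost,PG,true,50.40,30
pg_pc,latanoprost,PG,false,23.50,90
bb_pf,timolol,BB,true,28.00,30
bb_pc,timolol,BB,false,12.00,90
cai_pf,dorzolamide,CAI,true,34.00,30
cai_pc,dorzolamide,CAI,false,21.00,90
a2a_pf,brimonidine,A2A,true,32.00,30
a2a_pc,brimonidine,A2A,false,18.00,90
tears_pf,hypromellose,artificial_tears,true,15.00,30
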