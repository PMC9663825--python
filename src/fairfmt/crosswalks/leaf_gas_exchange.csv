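target_format,source_standard,source_term,target_term,unit_factor,unit_offset,notes
leaf_gas_exchange,li6400,Photo,A,1,0,net assimilation
leaf_gas_exchange,li6400,Cond,gsw,1,0,stomatal conductance
leaf_gas_exchange,li6400,Ci,Ci,1,0,identity
leaf_gas_exchange,li6400,Tleaf,Tleaf,1,0,identity
leaf_gas_exchange,li6400,PARi,Qin,1,0,incident PAR
leaf_gas_exchange,li6800,A,A,1,0,already harmonized
leaf_gas_exchange,li6800,gsw,gsw,1,0,already harmonized
leaf_gas_exchange,li6800,Ci,Ci,1,0,identity
leaf_gas_exchange,li6800,Tleaf,Tleaf,1,0,identity
leaf_gas_exchange,li6800,Qin,Qin,1,0,identity
leaf_gas_exchange,li6252,CO2_assim,A,1,0,
leaf_gas_exchange,li6252,g_s,gsw,1,0,
leaf_gas_exchange,li6252,leaf_temp,Tleaf,1,0,
leaf_gas_exchange,ciras2,An,A,1,0,
leaf_gas_exchange,ciras2,gs,gsw,0.001,0,reported in mmol m-2 s-1
leaf_gas_exchange,ciras2,ci,Ci,1,0,
leaf_gas_exchange,ciras2,Tl,Tleaf,1,0,
leaf_gas_exchange,ciras2,PARtop,Qin,1,0,
leaf_gas_exchange,ciras3,Anet,A,1,0,
leaf_gas_exchange,ciras3,gs_w,gsw,0.001,0,reported in mmol m-2 s-1
leaf_gas_exchange,ciras3,Ci_calc,Ci,1,0,
leaf_gas_exchange,ciras3,Tleaf_C,Tleaf,1,0,
leaf_gas_exchange,ciras3,Q_leaf,Qin,1,0,
leaf_gas_exchange,gfs3000,Assimilation,A,1,0,
leaf_gas_exchange,gfs3000,GH2O,gsw,0.001,0,reported in mmol m-2 s-1
leaf_gas_exchange,gfs3000,ci_ppm,Ci,1,0,
leaf_gas_exchange,gfs3000,Tcuv,Tleaf,1,0,cuvette temperature used as leaf proxy
leaf_gas_exchange,gfs3000,PARamb,Qin,1,0,
leaf_gas_exchange,lcpro_sd,photo_rate,A,1,0,
leaf_gas_exchange,lcpro_sd,stom_cond,gsw,1,0,
leaf_gas_exchange,lcpro_sd,int_co2,Ci,1,0,
leaf_gas_exchange,lcpro_sd,Tch,Tleaf,1,0,
leaf_gas_exchange,lci_t,Amax,A,1,0,
leaf_gas_exchange,lci_t,gsc,gsw,1.6,0,CO2 conductance scaled to water vapour
leaf_gas_exchange,lci_t,ci_int,Ci,1,0,
leaf_gas_exchange,targas1,net_photo,A,1,0,
leaf_gas_exchange,targas1,cond_h2o,gsw,1,0,
leaf_gas_exchange,targas1,t_leaf,Tleaf,1,0,
leaf_gas_exchange,targas1,par_i,Qin,1,0,
leaf_gas_exchange,q_box_co2,dCO2_flux,A,1,0,
leaf_gas_exchange,q_box_co2,g_stom,gsw,1,0,
leaf_gas_exchange,q_box_co2,T_leaf_meas,Tleaf,1,0,
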