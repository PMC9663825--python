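target_format,source_standard,source_term,target_term,unit_factor,unit_offset,notes
water_soil_chemistry,wqx,CharacteristicName,analyte,1,0,
water_soil_chemistry,wqx,ResultMeasureValue,value,1,0,
water_soil_chemistry,wqx,ResultMeasure_MeasureUnitCode,unit,1,0,
water_soil_chemistry,wqx,ActivityMediaName,matrix,1,0,
water_soil_chemistry,wqx,MonitoringLocationIdentifier,sample_id,1,0,closest WQX analogue
water_soil_chemistry,wqx,ResultDetectionConditionText,below_detection_flag,1,0,
water_soil_chemistry,wqx,DetectionQuantitationLimitMeasure_MeasureValue,detection_limit,1,0,
water_soil_chemistry,earthchem,SAMPLE_ID,sample_id,1,0,
water_soil_chemistry,earthchem,IGSN,igsn,1,0,
water_soil_chemistry,earthchem,ITEM,analyte,1,0,
water_soil_chemistry,earthchem,VALUE,value,1,0,
water_soil_chemistry,earthchem,UNITS,unit,1,0,
water_soil_chemistry,earthchem,METHOD,method,1,0,
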