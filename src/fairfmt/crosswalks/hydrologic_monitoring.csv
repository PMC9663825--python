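target_format,source_standard,source_term,target_term,unit_factor,unit_offset,notes
hydrologic_monitoring,wqx,ValueDateTime,datetime,1,0,date and time of observation
hydrologic_monitoring,wqx,MonitoringLocationIdentifier,site_id,1,0,
hydrologic_monitoring,wqx,ResultMeasureValue,water_level,1,0,when characteristic is gage height in m
hydrologic_monitoring,cuahsi_his,DateTimeUTC,datetime,1,0,
hydrologic_monitoring,cuahsi_his,SiteCode,site_id,1,0,
hydrologic_monitoring,cuahsi_his,DataValue,water_level,1,0,
hydrologic_monitoring,usgs_nwis,datetime,datetime,1,0,identity
hydrologic_monitoring,usgs_nwis,site_no,site_id,1,0,
hydrologic_monitoring,usgs_nwis,gage_height_ft,water_level,0.3048,0,feet to metres
hydrologic_monitoring,usgs_nwis,temp_f,temperature,0.5555555556,-17.7777777778,Fahrenheit to Celsius
hydrologic_monitoring,usgs_nwis,ph,pH,1,0,
hydrologic_monitoring,campbell_logger,TIMESTAMP,datetime,1,0,
hydrologic_monitoring,campbell_logger,StationID,site_id,1,0,
hydrologic_monitoring,campbell_logger,Lvl_m,water_level,1,0,
hydrologic_monitoring,campbell_logger,T_C,temperature,1,0,
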